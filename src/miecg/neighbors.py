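"""Verlet neighbour list with a displacement-triggered rebuild contract.

Pairs within ``cutoff + skin`` are kept; the list is rebuilt when any site
has moved more than ``skin/2`` since the last build, or when the box has
changed by more than ``skin/4`` (barostat moves sites implicitly).
"""

from __future__ import annotations

import numpy as np


class NeighborList:
    def __init__(self, cutoff: float, skin: float = 2.0):
        if cutoff <= 0 or skin < 0:
            raise ValueError("cutoff must be > 0 and skin >= 0")
        self.cutoff = cutoff
        self.skin = skin
        self.pairs_i = np.zeros(0, dtype=int)
        self.pairs_j = np.zeros(0, dtype=int)
        self._ref_positions = None
        self._ref_box = None
        self.n_builds = 0

    def build(self, positions: np.ndarray, box: np.ndarray):
        from scipy.spatial import cKDTree

        box = np.asarray(box, dtype=float)
        rlist = self.cutoff + self.skin
        if rlist > 0.5 * float(np.min(box)) + 1e-9:
            raise ValueError(
                f"cutoff+skin {rlist:.3f} Å exceeds half the shortest box edge"
            )
        pts = np.mod(positions, box)
        pts = np.where(pts >= box, 0.0, pts)  # exact-boundary guard for boxsize
        tree = cKDTree(pts, boxsize=box)
        pairs = tree.query_pairs(rlist, output_type="ndarray")
        if len(pairs):
            self.pairs_i = np.ascontiguousarray(pairs[:, 0])
            self.pairs_j = np.ascontiguousarray(pairs[:, 1])
        else:
            self.pairs_i = np.zeros(0, dtype=int)
            self.pairs_j = np.zeros(0, dtype=int)
        self._ref_positions = positions.copy()
        self._ref_box = box.copy()
        self.n_builds += 1

    def needs_rebuild(self, positions: np.ndarray, box: np.ndarray) -> bool:
        if self._ref_positions is None or len(positions) != len(self._ref_positions):
            return True
        if np.max(np.abs(np.asarray(box) - self._ref_box)) > self.skin / 4.0:
            return True
        disp = positions - self._ref_positions
        max_sq = float(np.max(np.einsum("ij,ij->i", disp, disp)))
        return max_sq > (self.skin / 2.0) ** 2

    def update(self, positions: np.ndarray, box: np.ndarray):
        if self.needs_rebuild(positions, box):
            self.build(positions, box)

    def pairs(self):
        return self.pairs_i, self.pairs_j
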