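"""In-memory containers: topology and dynamical state."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .forcefield import BondedTerm, ForceField


class TopologyError(ValueError):
    pass


@dataclass
class Topology:
    """A built system: site types, coordinates, molecules, bonded terms, box.

    ``type_names`` maps the integer ``type_ids`` onto force-field site-type
    labels.  ``rigid_waters`` holds (O, H, H) index triplets integrated as
    rigid SPC/E molecules (no bonded terms; distance constraints instead).
    """

    type_names: list
    type_ids: np.ndarray  # (N,) int
    positions: np.ndarray  # (N,3) Å
    molecule_ids: np.ndarray  # (N,) int
    molecule_species: list  # species label per molecule id
    bonded_terms: list = field(default_factory=list)  # list[BondedTerm]
    rigid_waters: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))
    box: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.type_ids = np.asarray(self.type_ids, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        self.rigid_waters = np.asarray(self.rigid_waters, dtype=int).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.positions)
        if len(self.type_ids) != n or len(self.molecule_ids) != n:
            raise TopologyError("type_ids / molecule_ids length mismatch")
        for t in self.bonded_terms:
            mols = {self.molecule_ids[i] for i in t.sites}
            if len(mols) != 1:
                raise TopologyError(f"bonded term {t.sites} spans molecules {mols}")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_ids.max()) + 1 if self.n_sites else 0

    def site_type_labels(self) -> np.ndarray:
        return np.array(self.type_names, dtype=object)[self.type_ids]

    def masses(self, ff: ForceField) -> np.ndarray:
        table = np.array([ff.site_types[t].mass for t in self.type_names])
        return table[self.type_ids]

    def charges(self, ff: ForceField) -> np.ndarray:
        table = np.array([ff.site_types[t].charge for t in self.type_names])
        return table[self.type_ids]

    def total_mass(self, ff: ForceField) -> float:
        return float(self.masses(ff).sum())

    def net_charge(self, ff: ForceField) -> float:
        return float(self.charges(ff).sum())

    # -- exclusions ------------------------------------------------------------

    def bond_graph_edges(self) -> np.ndarray:
        """Bonds plus rigid-water constraint edges, as an (E,2) array."""
        edges = [t.sites for t in self.bonded_terms if t.kind == "bond"]
        for (o, h1, h2) in self.rigid_waters:
            edges.append((o, h1))
            edges.append((o, h2))
        return np.array(edges, dtype=int).reshape(-1, 2)

    def excluded_pairs(self, exclude12=True, exclude13=True) -> np.ndarray:
        """Unordered site pairs removed from nonbonded sums (1-2 and 1-3)."""
        edges = self.bond_graph_edges()
        neigh = {}
        for a, b in edges:
            neigh.setdefault(int(a), set()).add(int(b))
            neigh.setdefault(int(b), set()).add(int(a))
        pairs = set()
        if exclude12:
            for a, b in edges:
                pairs.add((min(int(a), int(b)), max(int(a), int(b))))
        if exclude13:
            for mid, nbrs in neigh.items():
                nbrs = sorted(nbrs)
                for i in range(len(nbrs)):
                    for j in range(i + 1, len(nbrs)):
                        pairs.add((nbrs[i], nbrs[j]))
        return np.array(sorted(pairs), dtype=int).reshape(-1, 2)

    # -- audits ---------------------------------------------------------------

    def term_counts(self) -> dict:
        return {
            "bond": sum(1 for t in self.bonded_terms if t.kind == "bond"),
            "bend": sum(1 for t in self.bonded_terms if t.kind == "bend"),
            "dihedral": sum(1 for t in self.bonded_terms if t.kind == "dihedral"),
        }

    def min_separation(self) -> float:
        """Smallest min-image pair distance (for build audits; O(N²) in chunks)."""
        n = self.n_sites
        if n < 2:
            return np.inf
        best = np.inf
        box = self.box if np.all(self.box > 0) else None
        for start in range(0, n - 1, 512):
            stop = min(start + 512, n - 1)
            for i in range(start, stop):
                d = self.positions[i + 1 :] - self.positions[i]
                if box is not None:
                    d -= box * np.round(d / box)
                best = min(best, float(np.min(np.linalg.norm(d, axis=1))))
        return best

    # -- serialization ---------------------------------------------------------

    def to_json(self, path):
        doc = {
            "type_names": self.type_names,
            "type_ids": self.type_ids.tolist(),
            "positions": np.round(self.positions, 9).tolist(),
            "molecule_ids": self.molecule_ids.tolist(),
            "molecule_species": list(self.molecule_species),
            "bonded_terms": [
                {"kind": t.kind, "sites": list(t.sites), "params": list(t.params)}
                for t in self.bonded_terms
            ],
            "rigid_waters": self.rigid_waters.tolist(),
            "box": self.box.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "Topology":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            type_names=doc["type_names"],
            type_ids=np.array(doc["type_ids"], dtype=int),
            positions=np.array(doc["positions"], dtype=float),
            molecule_ids=np.array(doc["molecule_ids"], dtype=int),
            molecule_species=doc["molecule_species"],
            bonded_terms=[
                BondedTerm(t["kind"], tuple(t["sites"]), tuple(t["params"]))
                for t in doc["bonded_terms"]
            ],
            rigid_waters=np.array(doc["rigid_waters"], dtype=int).reshape(-1, 3),
            box=np.array(doc["box"], dtype=float),
        )


@dataclass
class SystemState:
    """Dynamical state of a simulation: coordinates, velocities, box, extended variables."""

    topology: Topology
    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray
    thermo_eta: float = 0.0  # thermostat position (log of scale integral)
    thermo_veta: float = 0.0  # thermostat velocity
    baro_veps: float = 0.0  # barostat strain rate
    step: int = 0
    seed: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @classmethod
    def from_topology(cls, top: Topology, seed: int = 0) -> "SystemState":
        return cls(
            topology=top,
            positions=top.positions.copy(),
            velocities=np.zeros_like(top.positions),
            box=top.box.copy(),
            seed=seed,
        )

    def copy(self) -> "SystemState":
        return SystemState(
            topology=self.topology,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            box=self.box.copy(),
            thermo_eta=self.thermo_eta,
            thermo_veta=self.thermo_veta,
            baro_veps=self.baro_veps,
            step=self.step,
            seed=self.seed,
        )
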