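"""Trajectory analysis: equilibration detection, densities, MABD, RDFs.

Density is computed as total molar mass over the average post-equilibration
volume; its uncertainty is propagated from the standard deviation of the
volumes.  MABD (mean absolute percentage deviation) uses the simulated
density in the denominator: ``100·|ρ_md − ρ_ref|/ρ_md`` — deliberately
asymmetric, matching how the reference comparison is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .system import Topology
from .units import AVOG_CM3


@dataclass
class ObservableSeries:
    """A time series of one scalar observable."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class EquilibrationResult:
    index: int
    equilibrated: bool
    threshold: float


def detect_equilibration(series: ObservableSeries, threshold: float = 1.0,
                         n_candidates: int = 20) -> EquilibrationResult:
    """First index after which the series is statistically flat.

    Scans candidate start points; at each, the remaining samples are split
    into two blocks and the start is accepted when the block means differ by
    less than ``threshold`` pooled block standard errors.  A series that
    stays trending to the end is returned flagged ``equilibrated=False``
    (index = last candidate), not raised.
    """
    v = series.values
    n = len(v)
    if n < 20:
        raise ValueError("need at least 20 samples")
    candidates = np.unique(np.linspace(0, n - 16, n_candidates).astype(int))
    for start in candidates:
        rest = v[start:]
        half = len(rest) // 2
        a, b = rest[:half], rest[half:]
        spread = np.sqrt((a.std(ddof=1) ** 2 / len(a)) + (b.std(ddof=1) ** 2 / len(b)))
        scale = max(spread, 1e-12 * max(abs(float(np.mean(rest))), 1.0))
        if abs(a.mean() - b.mean()) <= threshold * scale:
            return EquilibrationResult(int(start), True, threshold)
    return EquilibrationResult(int(candidates[-1]), False, threshold)


@dataclass
class DensityReport:
    T: float
    rho_md: float
    rho_err: float
    rho_ref: float | None = None
    mabd: float | None = None

    def __post_init__(self):
        if self.rho_md <= 0:
            raise ValueError("density must be positive")
        if self.mabd is not None and self.mabd < 0:
            raise ValueError("MABD must be non-negative")


def average_density(volumes, total_mass: float, T: float,
                    eq_index: int = 0, rho_ref: float | None = None) -> DensityReport:
    """ρ = M/⟨V⟩ (g·cm⁻³) over the post-equilibration window, with the error
    propagated from std(V): σ_ρ = ρ·σ_V/⟨V⟩."""
    volumes = np.asarray(volumes, dtype=float)
    if eq_index < 0 or eq_index >= len(volumes):
        raise ValueError("empty post-equilibration window")
    window = volumes[eq_index:]
    v_mean = float(window.mean())
    v_std = float(window.std(ddof=1)) if len(window) > 1 else 0.0
    rho = total_mass / (AVOG_CM3 * v_mean)
    rho_err = rho * v_std / v_mean
    rep = DensityReport(T=T, rho_md=rho, rho_err=rho_err, rho_ref=rho_ref)
    if rho_ref is not None:
        rep.mabd = mabd(rho, rho_ref)
    return rep


def mabd(rho_md, rho_ref) -> float:
    """Absolute percentage deviation, MD value in the denominator.

    Vector inputs give the mean over per-temperature values.
    """
    rho_md = np.asarray(rho_md, dtype=float)
    rho_ref = np.asarray(rho_ref, dtype=float)
    if np.any(rho_md <= 0) or np.any(rho_ref <= 0):
        raise ValueError("densities must be positive")
    val = 100.0 * np.abs(rho_md - rho_ref) / rho_md
    return float(np.mean(val))


def density_vs_temperature(reports) -> pd.DataFrame:
    """Tabulate density reports against temperature (sorted, with MABD column).

    Adds a ``monotonic_decreasing`` attribute flag in ``df.attrs``.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 temperatures")
    temps = [r.T for r in reports]
    if len(set(temps)) != len(temps):
        raise ValueError("duplicate temperatures")
    rows = [{"T": r.T, "MD": r.rho_md, "err": r.rho_err,
             "EXP": r.rho_ref, "MABD": r.mabd} for r in reports]
    df = pd.DataFrame(rows).sort_values("T").reset_index(drop=True)
    df.attrs["monotonic_decreasing"] = bool(np.all(np.diff(df["MD"].values) < 0))
    return df


# --- radial distribution functions -------------------------------------------


@dataclass
class RDFResult:
    pair: tuple
    r: np.ndarray            # bin centres, Å
    g: np.ndarray            # dimensionless
    n_frames: int
    dr: float
    rmax: float
    pair_counts: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def first_peak(self, r_min: float = 0.0, r_max: float | None = None):
        """(r, g) at the maximum of g within [r_min, r_max].

        Bound ``r_max`` to the first coordination shell when comparing peak
        heights between site pairs; an unbounded maximum picks up long-range
        noise for weakly correlated pairs.
        """
        mask = self.r >= r_min
        if r_max is not None:
            mask &= self.r <= r_max
        k = int(np.argmax(self.g[mask]))
        return float(self.r[mask][k]), float(self.g[mask][k])


def rdf(frames, topology: Topology, type_a: str, type_b: str,
        dr: float = 0.1, rmax: float | None = None) -> RDFResult:
    """Site–site g(r) averaged over frames.

    ``frames`` is an iterable of (positions, box).  Distinct-type pairs are
    counted once per unordered pair and normalised by N_a·N_b/V; the
    same-type normalisation uses N(N−1)/2.  Intramolecular pairs are
    included (the CG sites of interest sit on different molecules).
    """
    labels = topology.site_type_labels()
    sel_a = np.flatnonzero(labels == type_a)
    sel_b = np.flatnonzero(labels == type_b)
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError(f"no sites of type {type_a!r} or {type_b!r}")
    same = type_a == type_b

    first = True
    counts = None
    n_frames = 0
    norm_acc = 0.0
    for positions, box in frames:
        box = np.asarray(box, dtype=float)
        if rmax is None:
            rmax = 0.5 * float(box.min())
        if rmax > 0.5 * box.min() + 1e-9:
            raise ValueError("rmax exceeds half the smallest box edge")
        if first:
            edges = np.arange(0.0, rmax + dr, dr)
            edges = edges[edges <= rmax + 1e-12]
            counts = np.zeros(len(edges) - 1)
            first = False
        pa = np.mod(positions[sel_a], box)
        pa = np.where(pa >= box, 0.0, pa)
        tree_a = cKDTree(pa, boxsize=box)
        if same:
            pairs = tree_a.query_pairs(rmax, output_type="ndarray")
            if len(pairs):
                d = positions[sel_a[pairs[:, 0]]] - positions[sel_a[pairs[:, 1]]]
                d -= box * np.round(d / box)
                r = np.linalg.norm(d, axis=1)
                counts += np.histogram(r, bins=edges)[0]
            n_pairs_ideal = len(sel_a) * (len(sel_a) - 1) / 2.0
        else:
            pb = np.mod(positions[sel_b], box)
            pb = np.where(pb >= box, 0.0, pb)
            tree_b = cKDTree(pb, boxsize=box)
            pair_lists = tree_a.query_ball_tree(tree_b, rmax)
            ii = np.repeat(np.arange(len(sel_a)), [len(p) for p in pair_lists])
            jj = np.concatenate([np.asarray(p, dtype=int) for p in pair_lists]) \
                if len(ii) else np.zeros(0, int)
            if len(ii):
                d = positions[sel_a[ii]] - positions[sel_b[jj]]
                d -= box * np.round(d / box)
                r = np.linalg.norm(d, axis=1)
                counts += np.histogram(r, bins=edges)[0]
            n_pairs_ideal = float(len(sel_a) * len(sel_b))
        norm_acc += n_pairs_ideal / float(np.prod(box))
        n_frames += 1
    if n_frames == 0:
        raise ValueError("no frames")
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    # ⟨pair count in shell⟩ / (pair density × shell volume)
    g = counts / (norm_acc * shell)
    return RDFResult(pair=(type_a, type_b), r=centers, g=g, n_frames=n_frames,
                     dr=dr, rmax=float(rmax), pair_counts=counts)
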