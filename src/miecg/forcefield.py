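"""Mie-potential force field: pair parameters, mixing rules and bonded terms.

The van-der-Waals interaction between coarse-grained sites is the Mie
(generalised Lennard-Jones) potential

.. math::

    U(r) = \\frac{\\varepsilon}{n-m}
           \\left( m \\left(\\frac{r_0}{r}\\right)^n
                 - n \\left(\\frac{r_0}{r}\\right)^m \\right)

with repulsive exponent *n*, attractive exponent *m*, well depth ε and
well position r₀.  The collision diameter σ (where U crosses zero) is
related to r₀ by ``r0 = sigma * (n/m)**(1/(n-m))``.

Unlike pairs are combined with Lorentz–Berthelot rules (arithmetic σ,
geometric ε); exponents of unlike pairs are combined by an arithmetic mean
rounded to the nearest integer (configurable), since Lorentz–Berthelot does
not define them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml


class DegenerateExponentError(ValueError):
    """Raised when the Mie exponents n and m coincide."""


class ForceFieldError(ValueError):
    """Malformed force-field input."""


def r0_from_sigma(sigma: float, n: float, m: float) -> float:
    """Well position r₀ from the collision diameter σ."""
    if n == m:
        raise DegenerateExponentError("Mie exponents must differ (n != m)")
    if n <= 0 or m <= 0 or sigma <= 0:
        raise ValueError("sigma, n, m must be positive")
    return sigma * (n / m) ** (1.0 / (n - m))


def sigma_from_r0(r0: float, n: float, m: float) -> float:
    """Collision diameter σ from the well position r₀ (inverse of r0_from_sigma)."""
    if n == m:
        raise DegenerateExponentError("Mie exponents must differ (n != m)")
    if n <= 0 or m <= 0 or r0 <= 0:
        raise ValueError("r0, n, m must be positive")
    return r0 / (n / m) ** (1.0 / (n - m))


@dataclass(frozen=True)
class MieParams:
    """Parameters of one Mie pair interaction (kcal·mol⁻¹ and Å)."""

    epsilon: float
    n: float
    m: float
    r0: float
    sigma: float

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ForceFieldError("epsilon must be positive")
        if not (self.n > self.m >= 1):
            raise ForceFieldError("exponents must satisfy n > m >= 1")
        expected = r0_from_sigma(self.sigma, self.n, self.m)
        if abs(expected - self.r0) > 1e-10 * max(1.0, abs(self.r0)):
            raise ForceFieldError(
                f"r0={self.r0} inconsistent with sigma={self.sigma} "
                f"for exponents ({self.n}, {self.m})"
            )

    @classmethod
    def from_r0(cls, epsilon: float, n: float, m: float, r0: float) -> "MieParams":
        return cls(epsilon, n, m, r0, sigma_from_r0(r0, n, m))

    @classmethod
    def from_sigma(cls, epsilon: float, n: float, m: float, sigma: float) -> "MieParams":
        return cls(epsilon, n, m, r0_from_sigma(sigma, n, m), sigma)


def mie_energy(r, p: MieParams):
    """Mie pair energy at separation(s) ``r`` (Å), in kcal·mol⁻¹."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    x = p.r0 / r
    pref = p.epsilon / (p.n - p.m)
    u = pref * (p.m * x**p.n - p.n * x**p.m)
    return u if u.shape else float(u)


def mie_energy_force(r, p: MieParams):
    """Return ``(U, F)`` with ``F = -dU/dr`` (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    x = p.r0 / r
    xn = x**p.n
    xm = x**p.m
    pref = p.epsilon / (p.n - p.m)
    u = pref * (p.m * xn - p.n * xm)
    f = pref * p.n * p.m * (xn - xm) / r
    if u.shape:
        return u, f
    return float(u), float(f)


@dataclass(frozen=True)
class SiteType:
    """A coarse-grained site type: label, mass, partial charge, self-interaction.

    ``self_params`` may be None for sites with no van-der-Waals interaction
    (e.g. SPC/E hydrogen, which carries charge and mass only).
    """

    name: str
    mass: float
    charge: float
    self_params: MieParams | None

    def __post_init__(self):
        if self.mass < 0:
            raise ForceFieldError(f"site {self.name}: mass must be >= 0")


def _mix_exponents(na, ma, nb, mb, rule: str):
    if rule == "fixed":
        return float(na), float(ma)
    if rule != "arithmetic":
        raise ForceFieldError(f"unknown exponent mixing rule {rule!r}")
    m_ab = float(round((ma + mb) / 2.0))
    n_ab = float(round((na + nb) / 2.0))
    n_ab = max(n_ab, m_ab + 1.0)
    return n_ab, m_ab


def mix_params(a: SiteType, b: SiteType, exponent_mixing: str = "arithmetic") -> MieParams | None:
    """Lorentz–Berthelot cross parameters for an unlike pair.

    σ is the arithmetic mean, ε the geometric mean; exponents follow the
    declared mixing rule ('arithmetic' mean rounded to integer, floor m+1 for
    n, or 'fixed' = take the first site's exponents).  Returns None when
    either site has no vdW interaction.
    """
    pa, pb = a.self_params, b.self_params
    if pa is None or pb is None:
        return None
    if a.name == b.name:
        return pa
    sigma = 0.5 * (pa.sigma + pb.sigma)
    epsilon = float(np.sqrt(pa.epsilon * pb.epsilon))
    n, m = _mix_exponents(pa.n, pa.m, pb.n, pb.m, exponent_mixing)
    return MieParams.from_sigma(epsilon, n, m, sigma)


# --- bonded terms -------------------------------------------------------------

@dataclass(frozen=True)
class BondedTerm:
    """One bonded interaction.

    kind='bond':     params = (k [kcal·mol⁻¹·Å⁻²], r_ref [Å]);      U = ½k(r−r_ref)²
    kind='bend':     params = (k [kcal·mol⁻¹·rad⁻²], theta_ref [rad]); U = ½k(θ−θ_ref)²
    kind='dihedral': params = (k [kcal·mol⁻¹], multiplicity, delta [rad]);
                     U = k(1 + cos(p·φ − δ))
    """

    kind: str
    sites: tuple
    params: tuple

    def __post_init__(self):
        nsites = {"bond": 2, "bend": 3, "dihedral": 4}.get(self.kind)
        if nsites is None:
            raise ForceFieldError(f"unknown bonded term kind {self.kind!r}")
        if len(self.sites) != nsites or len(set(self.sites)) != nsites:
            raise ForceFieldError(f"{self.kind} needs {nsites} distinct site indices")
        if self.kind == "bond" and self.params[1] <= 0:
            raise ForceFieldError("bond reference length must be positive")


@dataclass
class ExclusionPolicy:
    """Which intramolecular nonbonded pairs are removed from the pair sums.

    1-2 and 1-3 neighbours (through bonds or rigid constraints) are excluded;
    1-4 neighbours are scaled by ``scale14`` (default 1.0 = fully included).
    """

    exclude12: bool = True
    exclude13: bool = True
    scale14: float = 1.0


@dataclass
class ForceField:
    """Registry of site types, mixing options and molecule templates."""

    site_types: dict = field(default_factory=dict)
    exponent_mixing: str = "arithmetic"
    exclusions: ExclusionPolicy = field(default_factory=ExclusionPolicy)
    molecules: dict = field(default_factory=dict)  # raw template dicts from the file

    def add_site_type(self, st: SiteType):
        if st.name in self.site_types:
            raise ForceFieldError(f"duplicate site type {st.name!r}")
        self.site_types[st.name] = st

    def type_names(self) -> list:
        return list(self.site_types)

    def pair_params(self, name_a: str, name_b: str) -> MieParams | None:
        return mix_params(
            self.site_types[name_a], self.site_types[name_b], self.exponent_mixing
        )

    def pair_tables(self, names: Sequence[str]):
        """Dense (T,T) arrays of ε, n, m, r0 for the listed type names.

        Pairs without a vdW interaction get ε = 0 (and dummy exponents).
        """
        t = len(names)
        eps = np.zeros((t, t))
        nn = np.full((t, t), 9.0)
        mm = np.full((t, t), 6.0)
        r0 = np.ones((t, t))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                p = self.pair_params(a, b)
                if p is not None:
                    eps[i, j] = p.epsilon
                    nn[i, j] = p.n
                    mm[i, j] = p.m
                    r0[i, j] = p.r0
        return eps, nn, mm, r0

    # -- loading ---------------------------------------------------------------

    @classmethod
    def from_dict(cls, doc: dict) -> "ForceField":
        ff = cls()
        mixing = doc.get("mixing", {})
        ff.exponent_mixing = mixing.get("exponent", "arithmetic")
        excl = doc.get("exclusions", {})
        ff.exclusions = ExclusionPolicy(
            exclude12=bool(excl.get("exclude12", True)),
            exclude13=bool(excl.get("exclude13", True)),
            scale14=float(excl.get("scale14", 1.0)),
        )
        for name, row in doc.get("site_types", {}).items():
            if row.get("epsilon", 0.0) > 0:
                params = MieParams.from_r0(
                    float(row["epsilon"]), float(row["n"]), float(row["m"]), float(row["r0"])
                )
            else:
                params = None
            ff.add_site_type(
                SiteType(name, float(row["mass"]), float(row.get("charge", 0.0)), params)
            )
        ff.molecules = dict(doc.get("molecules", {}))
        return ff

    @classmethod
    def from_yaml(cls, path=None) -> "ForceField":
        """Load a registry file; with no path, the packaged [bmim][Cl]+cellulose+water default."""
        if path is None:
            text = resources.files("miecg.data").joinpath("bmimcl_cg.yaml").read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        return cls.from_dict(yaml.safe_load(text))


def default_forcefield() -> ForceField:
    """The packaged default force field (ionic liquid + cellulose + SPC/E water)."""
    return ForceField.from_yaml(None)


# --- bonded energy/forces (vectorised over grouped term arrays) ---------------

def _min_image(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)


def bond_energy_forces(pos, idx, k, r_ref, box=None):
    """Harmonic bonds.  idx (B,2); returns (energy, forces (N,3))."""
    forces = np.zeros_like(pos)
    if len(idx) == 0:
        return 0.0, forces
    d = _min_image(pos[idx[:, 0]] - pos[idx[:, 1]], box)
    r = np.linalg.norm(d, axis=1)
    dr = r - r_ref
    energy = float(np.sum(0.5 * k * dr**2))
    fmag = -(k * dr) / r  # along d, applied to site 0
    fvec = fmag[:, None] * d
    np.add.at(forces, idx[:, 0], fvec)
    np.add.at(forces, idx[:, 1], -fvec)
    return energy, forces


def bend_energy_forces(pos, idx, k, theta_ref, box=None):
    """Harmonic angles.  idx (A,3) with the apex in the middle."""
    forces = np.zeros_like(pos)
    if len(idx) == 0:
        return 0.0, forces
    rij = _min_image(pos[idx[:, 0]] - pos[idx[:, 1]], box)
    rkj = _min_image(pos[idx[:, 2]] - pos[idx[:, 1]], box)
    nij = np.linalg.norm(rij, axis=1)
    nkj = np.linalg.norm(rkj, axis=1)
    cos_t = np.sum(rij * rkj, axis=1) / (nij * nkj)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    theta = np.arccos(cos_t)
    dtheta = theta - theta_ref
    energy = float(np.sum(0.5 * k * dtheta**2))
    # dU/dθ, then chain rule through cosθ; guard sinθ → 0
    sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 1e-12))
    coef = k * dtheta / sin_t  # -dU/dcosθ with the arccos chain rule sign folded in
    dcos_dri = rkj / (nij * nkj)[:, None] - rij * (cos_t / nij**2)[:, None]
    dcos_drk = rij / (nij * nkj)[:, None] - rkj * (cos_t / nkj**2)[:, None]
    fi = coef[:, None] * dcos_dri
    fk = coef[:, None] * dcos_drk
    np.add.at(forces, idx[:, 0], fi)
    np.add.at(forces, idx[:, 2], fk)
    np.add.at(forces, idx[:, 1], -(fi + fk))
    return energy, forces


def dihedral_energy_forces(pos, idx, k, mult, delta, box=None):
    """Cosine-series dihedrals U = k(1 + cos(pφ − δ)).  idx (D,4)."""
    forces = np.zeros_like(pos)
    if len(idx) == 0:
        return 0.0, forces
    b1 = _min_image(pos[idx[:, 1]] - pos[idx[:, 0]], box)
    b2 = _min_image(pos[idx[:, 2]] - pos[idx[:, 1]], box)
    b3 = _min_image(pos[idx[:, 3]] - pos[idx[:, 2]], box)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(np.cross(n1, n2) * b2, axis=1) / nb2
    phi = np.arctan2(y, x)
    energy = float(np.sum(k * (1.0 + np.cos(mult * phi - delta))))
    dU = -k * mult * np.sin(mult * phi - delta)  # dU/dφ
    sq1 = np.sum(n1 * n1, axis=1)
    sq2 = np.sum(n2 * n2, axis=1)
    sq1 = np.maximum(sq1, 1e-12)
    sq2 = np.maximum(sq2, 1e-12)
    # standard analytic gradient of the torsion angle
    dphi_d1 = -(nb2 / sq1)[:, None] * n1
    dphi_d4 = (nb2 / sq2)[:, None] * n2
    s12 = np.sum(b1 * b2, axis=1) / nb2**2
    s32 = np.sum(b3 * b2, axis=1) / nb2**2
    dphi_d2 = -(1.0 + s12)[:, None] * dphi_d1 + s32[:, None] * dphi_d4
    dphi_d3 = s12[:, None] * dphi_d1 - (1.0 + s32)[:, None] * dphi_d4
    for col, g in zip(range(4), (dphi_d1, dphi_d2, dphi_d3, dphi_d4)):
        np.add.at(forces, idx[:, col], -dU[:, None] * g)
    return energy, forces


def group_bonded_terms(terms: Sequence[BondedTerm]):
    """Split a list of BondedTerm into dense arrays per kind for fast evaluation."""
    bonds = [t for t in terms if t.kind == "bond"]
    bends = [t for t in terms if t.kind == "bend"]
    dihedrals = [t for t in terms if t.kind == "dihedral"]

    def _pack(ts, npar):
        idx = np.array([t.sites for t in ts], dtype=int).reshape(len(ts), -1)
        pars = [np.array([t.params[i] for t in ts], dtype=float) for i in range(npar)]
        return (idx, *pars)

    return {
        "bond": _pack(bonds, 2) if bonds else (np.zeros((0, 2), int), np.zeros(0), np.zeros(0)),
        "bend": _pack(bends, 2) if bends else (np.zeros((0, 3), int), np.zeros(0), np.zeros(0)),
        "dihedral": _pack(dihedrals, 3)
        if dihedrals
        else (np.zeros((0, 4), int), np.zeros(0), np.zeros(0), np.zeros(0)),
    }


def bonded_energy_forces(pos, terms: Sequence[BondedTerm], box=None):
    """Total bonded energy and forces for a term list.

    Returns (per-kind energy dict, forces).
    """
    n = len(pos)
    for t in terms:
        if max(t.sites) >= n or min(t.sites) < 0:
            raise ForceFieldError(f"bonded term indices {t.sites} out of range")
    grouped = group_bonded_terms(terms)
    e = {}
    forces = np.zeros_like(np.asarray(pos, dtype=float))
    idx, k, r_ref = grouped["bond"]
    e["bond"], f = bond_energy_forces(pos, idx, k, r_ref, box)
    forces += f
    idx, k, th = grouped["bend"]
    e["bend"], f = bend_energy_forces(pos, idx, k, th, box)
    forces += f
    idx, k, mult, delta = grouped["dihedral"]
    e["dihedral"], f = dihedral_energy_forces(pos, idx, k, mult, delta, box)
    forces += f
    return e, forces
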