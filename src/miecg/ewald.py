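"""Ewald summation for point charges in an orthorhombic periodic box.

The Coulomb energy is split into a short-range real-space sum (erfc-screened,
truncated at a cutoff), a reciprocal-space sum over k-vectors bounded by
integer limits (kmax1, kmax2, kmax3), and the self-energy.  Excluded
intramolecular pairs are handled by subtracting their erf-screened
interaction (the part implicitly included by the reciprocal sum).

All energies are in kcal·mol⁻¹, forces in kcal·mol⁻¹·Å⁻¹, and the virial is
returned as the trace ``Σ f·r`` entering ``P = (2K + W)/(3V)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf, erfc

from . import _kernels
from .units import COULOMB

_TWO_OVER_SQRT_PI = 2.0 / np.sqrt(np.pi)


class NeutralityError(ValueError):
    """The Ewald sum requires a charge-neutral system."""


class GeometryError(ValueError):
    """Cutoff or box geometry is inconsistent with minimum-image periodicity."""


@dataclass(frozen=True)
class EwaldConfig:
    """Ewald parameters: convergence parameter α (Å⁻¹), k-space limits, real cutoff (Å)."""

    alpha: float = 0.18520
    kmax: tuple = (8, 8, 16)
    real_cutoff: float = 15.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if len(self.kmax) != 3 or any(int(k) < 1 for k in self.kmax):
            raise ValueError("kmax must be three integers >= 1")
        if self.real_cutoff <= 0:
            raise ValueError("real cutoff must be positive")


def _check_box(box, cutoff):
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise GeometryError("box edges must be positive")
    if cutoff > 0.5 * box.min() + 1e-9:
        raise GeometryError(
            f"real-space cutoff {cutoff} Å exceeds half the shortest box edge "
            f"({0.5 * box.min():.3f} Å)"
        )
    return box


def half_space_kvectors(box, kmax):
    """Reciprocal vectors of the half space (each ±k pair counted once), with weights 2.

    Returns (kvecs (K,3) in Å⁻¹, ksq (K,)).
    """
    box = np.asarray(box, dtype=float)
    k1, k2, k3 = (int(k) for k in kmax)
    n1, n2, n3 = np.meshgrid(
        np.arange(-k1, k1 + 1), np.arange(-k2, k2 + 1), np.arange(-k3, k3 + 1),
        indexing="ij",
    )
    n = np.stack([n1.ravel(), n2.ravel(), n3.ravel()], axis=1)
    # keep one of each ±n pair: lexicographically positive
    keep = (n[:, 0] > 0) | ((n[:, 0] == 0) & (n[:, 1] > 0)) | (
        (n[:, 0] == 0) & (n[:, 1] == 0) & (n[:, 2] > 0)
    )
    n = n[keep]
    kvecs = 2.0 * np.pi * n / box[None, :]
    ksq = np.sum(kvecs**2, axis=1)
    return kvecs, ksq


def ewald_real(dr_vec, dr, qprod, alpha):
    """Real-space contribution for precomputed pair separations.

    dr_vec (P,3), dr (P,), qprod (P,) = q_i q_j.  Returns (energy,
    per-pair force vectors on site i, virial).
    """
    if len(dr) == 0:
        return 0.0, np.zeros((0, 3)), 0.0
    e_pair = COULOMB * qprod * erfc(alpha * dr) / dr
    energy = float(np.sum(e_pair))
    # -dU/dr: derivative of erfc(a r)/r
    fmag = COULOMB * qprod * (
        erfc(alpha * dr) / dr**2 + _TWO_OVER_SQRT_PI * alpha * np.exp(-(alpha * dr) ** 2) / dr
    )
    fvec = (fmag / dr)[:, None] * dr_vec
    virial = float(np.sum(fmag * dr))
    return energy, fvec, virial


def ewald_reciprocal(positions, charges, box, cfg: EwaldConfig, chunk=1024):
    """Reciprocal-space energy, forces and virial."""
    box = np.asarray(box, dtype=float)
    if _kernels.HAVE_NUMBA:
        k1, k2, k3 = (int(k) for k in cfg.kmax)
        e, f, w = _kernels.recip_kernel(
            np.ascontiguousarray(positions, dtype=float),
            np.ascontiguousarray(charges, dtype=float),
            box, k1, k2, k3, float(cfg.alpha),
        )
        return COULOMB * e, COULOMB * f, COULOMB * w
    volume = float(np.prod(box))
    kvecs, ksq = half_space_kvectors(box, cfg.kmax)
    pref = 2.0 * (2.0 * np.pi / volume) * np.exp(-ksq / (4.0 * cfg.alpha**2)) / ksq
    energy = 0.0
    virial = 0.0
    forces = np.zeros_like(positions)
    for start in range(0, len(kvecs), chunk):
        kc = kvecs[start : start + chunk]
        pc = pref[start : start + chunk]
        ksqc = ksq[start : start + chunk]
        phase = positions @ kc.T  # (N, K)
        cosp = np.cos(phase)
        sinp = np.sin(phase)
        re_s = charges @ cosp  # (K,)
        im_s = charges @ sinp
        ek = pc * (re_s**2 + im_s**2)
        energy += float(np.sum(ek))
        virial += float(np.sum(ek * (1.0 - ksqc / (2.0 * cfg.alpha**2))))
        # F_i = Σ_k C_k 2 q_i k Im(e^{ik·r_i} S*)   (the 2 from d|S|²)
        imag = sinp * re_s[None, :] - cosp * im_s[None, :]  # (N,K)
        coeff = 2.0 * charges[:, None] * imag * pc[None, :]
        forces += coeff @ kc
    return COULOMB * energy, COULOMB * forces, COULOMB * virial


def ewald_self(charges, alpha):
    return -COULOMB * alpha / np.sqrt(np.pi) * float(np.sum(charges**2))


def ewald_excluded_correction(positions, charges, box, pairs, alpha):
    """Subtract the erf-screened interaction of excluded intramolecular pairs.

    pairs: (P,2) integer array.  Returns (energy, forces, virial); the energy
    is negative of the reciprocal-space inclusion of those pairs.
    """
    forces = np.zeros_like(positions)
    if len(pairs) == 0:
        return 0.0, forces, 0.0
    box = np.asarray(box, dtype=float)
    d = positions[pairs[:, 0]] - positions[pairs[:, 1]]
    d -= box * np.round(d / box)
    r = np.linalg.norm(d, axis=1)
    qprod = charges[pairs[:, 0]] * charges[pairs[:, 1]]
    mask = np.abs(qprod) > 0
    if not np.any(mask):
        return 0.0, forces, 0.0
    d, r, qprod = d[mask], r[mask], qprod[mask]
    pairs = pairs[mask]
    energy = float(np.sum(-COULOMB * qprod * erf(alpha * r) / r))
    # U_corr = -ke q q erf(αr)/r ;  F = -dU/dr along d
    fmag = -COULOMB * qprod * (
        erf(alpha * r) / r**2 - _TWO_OVER_SQRT_PI * alpha * np.exp(-(alpha * r) ** 2) / r
    )
    fvec = (fmag / r)[:, None] * d
    np.add.at(forces, pairs[:, 0], fvec)
    np.add.at(forces, pairs[:, 1], -fvec)
    virial = float(np.sum(fmag * r))
    return energy, forces, virial


def ewald_energy_forces(positions, charges, box, cfg: EwaldConfig, excluded_pairs=None):
    """Full Ewald sum on explicit pair lists built internally (O(N²) real space).

    Intended for small systems and as the reference path; the MD engine reuses
    its neighbour list instead.  Returns a dict of energy terms, forces and
    the virial trace.
    """
    positions = np.asarray(positions, dtype=float)
    charges = np.asarray(charges, dtype=float)
    box = _check_box(box, cfg.real_cutoff)
    if abs(charges.sum()) > 1e-8:
        raise NeutralityError(f"system net charge {charges.sum():g} != 0")
    n = len(positions)
    forces = np.zeros_like(positions)
    if np.all(charges == 0):
        zero = {"coulomb_real": 0.0, "coulomb_recip": 0.0, "coulomb_self": 0.0}
        return zero, forces, 0.0

    ii, jj = np.triu_indices(n, k=1)
    if excluded_pairs is not None and len(excluded_pairs):
        enc = ii * n + jj
        excl = np.asarray(excluded_pairs)
        encx = np.minimum(excl[:, 0], excl[:, 1]) * n + np.maximum(excl[:, 0], excl[:, 1])
        keep = ~np.isin(enc, encx)
        ii, jj = ii[keep], jj[keep]
    d = positions[ii] - positions[jj]
    d -= box * np.round(d / box)
    r = np.linalg.norm(d, axis=1)
    within = r <= cfg.real_cutoff
    ii, jj, d, r = ii[within], jj[within], d[within], r[within]
    qprod = charges[ii] * charges[jj]
    e_real, fvec, w_real = ewald_real(d, r, qprod, cfg.alpha)
    np.add.at(forces, ii, fvec)
    np.add.at(forces, jj, -fvec)

    e_recip, f_recip, w_recip = ewald_reciprocal(positions, charges, box, cfg)
    forces += f_recip
    e_self = ewald_self(charges, cfg.alpha)
    e_corr, f_corr, w_corr = ewald_excluded_correction(
        positions, charges, box,
        np.asarray(excluded_pairs) if excluded_pairs is not None else np.zeros((0, 2), int),
        cfg.alpha,
    )
    forces += f_corr
    energies = {
        "coulomb_real": e_real,
        "coulomb_recip": e_recip + e_corr,
        "coulomb_self": e_self,
    }
    return energies, forces, w_real + w_recip + w_corr
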