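"""Total-energy/force evaluator combining Mie pairs, Ewald and bonded terms.

The evaluator owns the per-type parameter tables, the exclusion list and the
Verlet neighbour list, so repeated calls during dynamics reuse all static
state.  The returned decomposition has the keys

    mie, coulomb_real, coulomb_recip, coulomb_self, bond, bend, dihedral

and the terms sum exactly to the total.  The virial trace ``W = Σ f·r``
(pair + reciprocal contributions) is returned for the barostat,
``P = (2K + W)/(3V)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .ewald import (
    EwaldConfig,
    NeutralityError,
    ewald_excluded_correction,
    ewald_real,
    ewald_reciprocal,
    ewald_self,
    _check_box,
)
from .forcefield import ForceField, bonded_energy_forces
from .neighbors import NeighborList
from .system import Topology

ENERGY_KEYS = ("mie", "coulomb_real", "coulomb_recip", "coulomb_self",
               "bond", "bend", "dihedral")


class SingularityError(RuntimeError):
    """Two interacting sites are (numerically) on top of each other."""


@dataclass
class EnergyReport:
    terms: dict

    @property
    def total(self) -> float:
        return float(sum(self.terms.values()))

    def __getitem__(self, key):
        return self.terms[key]


class ForceEvaluator:
    """Bound evaluator for one topology + force field + Ewald/cutoff settings."""

    def __init__(
        self,
        topology: Topology,
        ff: ForceField,
        cutoff: float = 15.0,
        ewald: EwaldConfig | None = None,
        skin: float = 2.0,
        switch_width: float = 1.0,
    ):
        self.topology = topology
        self.ff = ff
        self.cutoff = float(cutoff)
        self.switch_width = min(float(switch_width), 0.5 * self.cutoff)
        self.charges = topology.charges(ff)
        self.masses = topology.masses(ff)
        self.has_charges = bool(np.any(self.charges != 0.0))
        if self.has_charges and abs(self.charges.sum()) > 1e-8:
            raise NeutralityError(f"net charge {self.charges.sum():g} != 0")
        if ewald is None and self.has_charges:
            ewald = EwaldConfig(real_cutoff=self.cutoff)
        if ewald is not None and abs(ewald.real_cutoff - self.cutoff) > 1e-9:
            ewald = EwaldConfig(ewald.alpha, ewald.kmax, self.cutoff)
        self.ewald = ewald

        eps, nn, mm, r0 = ff.pair_tables(topology.type_names)
        self._eps, self._n, self._m, self._r0 = eps, nn, mm, r0
        self.type_ids = np.ascontiguousarray(topology.type_ids, dtype=np.int64)
        self.nlist = NeighborList(self.cutoff, skin)
        # the fused numba kernel assumes integer-valued Mie exponents (true
        # for the packaged set and the rounding mixing rule)
        self._use_pair_kernel = (
            _kernels.HAVE_NUMBA
            and np.all(nn == np.round(nn)) and np.all(mm == np.round(mm))
        )

        pol = ff.exclusions
        self.excluded = topology.excluded_pairs(pol.exclude12, pol.exclude13)
        n = topology.n_sites
        self._excl_code = (
            self.excluded[:, 0] * n + self.excluded[:, 1] if len(self.excluded) else
            np.zeros(0, dtype=int)
        )
        self.n_evaluations = 0

    # -- pieces ----------------------------------------------------------------

    def _scatter(self, forces, ii, jj, fvec):
        n = len(forces)
        for c in range(3):
            forces[:, c] += np.bincount(ii, weights=fvec[:, c], minlength=n)
            forces[:, c] -= np.bincount(jj, weights=fvec[:, c], minlength=n)

    def _filtered_pairs(self):
        """Current neighbour pairs with exclusions removed (cached per rebuild)."""
        if getattr(self, "_pairs_build", None) != self.nlist.n_builds:
            ii, jj = self.nlist.pairs()
            if len(self._excl_code):
                code = ii * self.topology.n_sites + jj
                keep = ~np.isin(code, self._excl_code)
                ii, jj = ii[keep], jj[keep]
            self._pairs_cache = (np.ascontiguousarray(ii), np.ascontiguousarray(jj))
            self._pairs_build = self.nlist.n_builds
        return self._pairs_cache

    def _pair_list(self, positions, box):
        self.nlist.update(positions, box)
        ii, jj = self._filtered_pairs()
        d = positions[ii] - positions[jj]
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=1)
        within = r <= self.cutoff
        ii, jj, d, r = ii[within], jj[within], d[within], r[within]
        if len(r) and float(r.min()) < 1e-6:
            k = int(np.argmin(r))
            raise SingularityError(
                f"sites {ii[k]} and {jj[k]} overlap (r = {r[k]:.2e} Å)"
            )
        return ii, jj, d, r

    def _mie(self, ii, jj, d, r, forces):
        ta = self.type_ids[ii]
        tb = self.type_ids[jj]
        eps = self._eps[ta, tb]
        active = eps > 0
        if not np.any(active):
            return 0.0, 0.0
        ii, jj, d, r = ii[active], jj[active], d[active], r[active]
        eps = eps[active]
        n = self._n[ta, tb][active]
        m = self._m[ta, tb][active]
        r0 = self._r0[ta, tb][active]
        x = r0 / r
        xn = x**n
        xm = x**m
        pref = eps / (n - m)
        u = pref * (m * xn - n * xm)
        fmag = pref * n * m * (xn - xm) / r  # -dU/dr
        # quintic switching to zero over [cutoff - switch_width, cutoff]:
        # keeps energy AND force continuous at the cutoff, which is what lets
        # NVE trajectories conserve energy through pair-list crossings.
        r_on = self.cutoff - self.switch_width
        in_win = r > r_on
        if np.any(in_win):
            t = (r[in_win] - r_on) / self.switch_width
            s = 1.0 - t**3 * (10.0 - 15.0 * t + 6.0 * t**2)
            ds_dr = -30.0 * t**2 * (1.0 - t) ** 2 / self.switch_width
            fmag[in_win] = fmag[in_win] * s - u[in_win] * ds_dr
            u[in_win] = u[in_win] * s
        fvec = (fmag / r)[:, None] * d
        self._scatter(forces, ii, jj, fvec)
        return float(np.sum(u)), float(np.sum(fmag * r))

    # -- main entry ------------------------------------------------------------

    def compute(self, positions: np.ndarray, box: np.ndarray):
        """Return (EnergyReport, forces (N,3), virial trace)."""
        positions = np.asarray(positions, dtype=float)
        box = _check_box(box, self.cutoff)
        forces = np.zeros_like(positions)
        terms = {k: 0.0 for k in ENERGY_KEYS}
        virial = 0.0
        do_coulomb = self.has_charges and self.ewald is not None

        if self._use_pair_kernel:
            self.nlist.update(positions, box)
            ii, jj = self._filtered_pairs()
            from .units import COULOMB

            e_mie, e_real, f_pair, w_pair, bad = _kernels.pair_kernel(
                positions, box, ii, jj, self.type_ids,
                self._eps, self._n, self._m, self._r0, self.charges,
                self.cutoff, self.switch_width,
                self.ewald.alpha if do_coulomb else 0.0,
                COULOMB if do_coulomb else 0.0,
            )
            if bad >= 0:
                raise SingularityError(
                    f"sites {ii[bad]} and {jj[bad]} overlap (r < 1e-6 Å)"
                )
            terms["mie"] = e_mie
            terms["coulomb_real"] = e_real
            forces += f_pair
            virial += w_pair
        else:
            ii, jj, d, r = self._pair_list(positions, box)
            terms["mie"], w = self._mie(ii, jj, d, r, forces)
            virial += w
            if do_coulomb:
                qprod = self.charges[ii] * self.charges[jj]
                charged = qprod != 0.0
                e_real, fvec, w_real = ewald_real(
                    d[charged], r[charged], qprod[charged], self.ewald.alpha
                )
                self._scatter(forces, ii[charged], jj[charged], fvec)
                terms["coulomb_real"] = e_real
                virial += w_real

        if do_coulomb:
            e_recip, f_recip, w_recip = ewald_reciprocal(
                positions, self.charges, box, self.ewald
            )
            e_corr, f_corr, w_corr = ewald_excluded_correction(
                positions, self.charges, box, self.excluded, self.ewald.alpha
            )
            terms["coulomb_recip"] = e_recip + e_corr
            terms["coulomb_self"] = ewald_self(self.charges, self.ewald.alpha)
            forces += f_recip + f_corr
            virial += w_recip + w_corr

        if self.topology.bonded_terms:
            eb, fb = bonded_energy_forces(positions, self.topology.bonded_terms, box)
            terms.update(eb)
            forces += fb
            # Each bonded term's forces sum to zero, so Σ f·r over unwrapped
            # coordinates is its virial; positions are never wrapped, so
            # molecules stay whole and this is exact.
            virial += float(np.sum(fb * positions))

        self.n_evaluations += 1
        return EnergyReport(terms), forces, virial


def total_energy_forces(topology: Topology, ff: ForceField, positions=None, box=None,
                        cutoff: float = 15.0, ewald: EwaldConfig | None = None):
    """One-shot evaluation helper (builds a ForceEvaluator internally)."""
    ev = ForceEvaluator(topology, ff, cutoff=cutoff, ewald=ewald)
    pos = topology.positions if positions is None else positions
    b = topology.box if box is None else box
    return ev.compute(pos, b)
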