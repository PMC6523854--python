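"""Built-in physics oracle checks, runnable via ``miecg validate``.

Each check recomputes a quantity with a known independent answer:
the Mie well depth and zero gradient at r₀, the rock-salt Madelung
constant via Ewald, analytic-vs-finite-difference forces, and short NVE
energy conservation.
"""

from __future__ import annotations

import numpy as np

from .calculator import ForceEvaluator
from .engine import EnsembleConfig, Integrator, initialize_velocities
from .ewald import EwaldConfig, ewald_energy_forces
from .fixtures import harmonic_dimer, mie_fluid, nacl_lattice
from .forcefield import default_forcefield, mie_energy_force
from .system import SystemState
from .units import COULOMB

MADELUNG_NACL = 1.747565


def check_mie_minimum() -> dict:
    ff = default_forcefield()
    worst = 0.0
    for st in ff.site_types.values():
        p = st.self_params
        if p is None:
            continue
        u, f = mie_energy_force(p.r0, p)
        worst = max(worst, abs(u + p.epsilon) / p.epsilon, abs(f))
    return {"passed": bool(worst < 1e-12), "max_error": float(worst)}


def check_madelung() -> dict:
    top, ff = nacl_lattice(8, spacing=2.82)
    cfg = EwaldConfig(alpha=2.0, kmax=(18, 18, 18), real_cutoff=2.8)
    terms, _, _ = ewald_energy_forces(top.positions, top.charges(ff), top.box, cfg)
    e_total = sum(terms.values())
    madelung = -e_total * 2.82 / (4.0 * COULOMB)
    rel = abs(madelung - MADELUNG_NACL) / MADELUNG_NACL
    return {"passed": bool(rel < 1e-4), "madelung": float(madelung), "rel_error": float(rel)}


def check_forces_fd(seed: int = 0) -> dict:
    top, ff = mie_fluid(30, density=0.004, seed=seed)
    ev = ForceEvaluator(top, ff, cutoff=8.0, skin=1.0)
    rng = np.random.default_rng(seed + 1)
    pos = top.positions + rng.normal(0, 0.2, top.positions.shape)
    _, forces, _ = ev.compute(pos, top.box)
    h = 1e-5
    worst = 0.0
    for _ in range(10):
        i = int(rng.integers(0, len(pos)))
        d = int(rng.integers(0, 3))
        pp = pos.copy()
        pp[i, d] += h
        pm = pos.copy()
        pm[i, d] -= h
        fd = -(ev.compute(pp, top.box)[0].total - ev.compute(pm, top.box)[0].total) / (2 * h)
        worst = max(worst, abs(fd - forces[i, d]) / max(abs(fd), 1e-6))
    return {"passed": bool(worst < 1e-6), "max_rel_error": float(worst)}


def check_nve_drift(seed: int = 0) -> dict:
    top, ff = harmonic_dimer()
    state = SystemState.from_topology(top, seed=seed)
    ev = ForceEvaluator(top, ff, cutoff=10.0)
    integ = Integrator(state, ev, EnsembleConfig(kind="NVE", dt=0.004, cutoff=10.0))
    energies = []
    for i in range(5000):
        integ.step_nve()
        if i % 50 == 0:
            energies.append(integ.report.total + integ.kinetic())
    energies = np.array(energies)
    scale = 0.5 * 0.5 * 0.5**2  # oscillation energy of the default dimer
    drift = (energies.max() - energies.min()) / scale
    return {"passed": bool(drift < 1e-5), "rel_drift": float(drift)}


def run_validation(seed: int = 0) -> dict:
    checks = {
        "mie_minimum": check_mie_minimum(),
        "madelung": check_madelung(),
        "forces_finite_difference": check_forces_fd(seed),
        "nve_drift": check_nve_drift(seed),
    }
    return {"all_passed": all(c["passed"] for c in checks.values()), "checks": checks}
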