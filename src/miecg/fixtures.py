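"""Deterministic small test systems.

These fixtures exercise each physics component in isolation: an ideal gas
(RDF/thermostat limits), a rock-salt ±1 lattice (Ewald vs. the Madelung
constant), a harmonic dimer (integrator accuracy), a Mie fluid (NVE/NVT
statistics), a scaled-down ionic-liquid box (density protocol) and a
mini solvated fiber that keeps the study composition ratios
(water : IL pairs : chains ≈ 3809 : 2826 : 36) at roughly 1/14 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builders import (
    CompositionSpec,
    build_bmimcl,
    build_fiber,
    solvate,
)
from .forcefield import (
    BondedTerm,
    ForceField,
    MieParams,
    SiteType,
    default_forcefield,
)
from .system import SystemState, Topology

FIXTURE_KINDS = ("ideal_gas", "nacl_lattice", "harmonic_dimer", "mie_fluid",
                 "il_box", "mini_fiber")

#: mini-fiber composition: the study ratios 3809:2826:36 scaled by ~1/14
MINI_FIBER_COMPOSITION = CompositionSpec(
    n_il_pairs=200, n_water=270, n_chains=4, n_cellobiose_per_chain=10
)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    n: int = 0
    box_edge: float = 0.0
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"choose from {FIXTURE_KINDS}")


def _gas_forcefield(epsilon=0.0, n=9.0, m=6.0, r0=4.0, mass=40.0, charge=0.0):
    ff = ForceField()
    params = MieParams.from_r0(epsilon, n, m, r0) if epsilon > 0 else None
    ff.add_site_type(SiteType("X", mass, charge, params))
    return ff


def _ion_forcefield():
    ff = ForceField()
    ff.add_site_type(SiteType("NA", 22.99, +1.0, None))
    ff.add_site_type(SiteType("CL", 35.453, -1.0, None))
    return ff


def ideal_gas(n: int = 1000, box_edge: float = 30.0, seed: int = 0):
    """Non-interacting point particles, uniform in the box."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box_edge, size=(n, 3))
    ff = _gas_forcefield(epsilon=0.0)
    top = Topology(
        type_names=ff.type_names(), type_ids=np.zeros(n, int), positions=pos,
        molecule_ids=np.arange(n), molecule_species=["gas"] * n,
        box=np.full(3, box_edge),
    )
    return top, ff


def nacl_lattice(n_ions: int = 8, spacing: float = 2.82):
    """Rock-salt ±1 lattice: alternating charges on a simple cubic grid.

    n_ions must be a perfect cube with even side (8, 64, ...); the cubic cell
    edge is side × spacing, so the structure tiles periodically.
    """
    side = round(n_ions ** (1 / 3))
    if side**3 != n_ions or side % 2:
        raise ValueError("n_ions must be a perfect cube with even side")
    coords, charges = [], []
    for i in range(side):
        for j in range(side):
            for k in range(side):
                coords.append((i * spacing, j * spacing, k * spacing))
                charges.append(1 if (i + j + k) % 2 == 0 else -1)
    coords = np.array(coords, dtype=float)
    charges = np.array(charges)
    ff = _ion_forcefield()
    type_ids = np.where(charges > 0, 0, 1)
    top = Topology(
        type_names=ff.type_names(), type_ids=type_ids, positions=coords,
        molecule_ids=np.arange(n_ions), molecule_species=["ion"] * n_ions,
        box=np.full(3, side * spacing),
    )
    return top, ff


def harmonic_dimer(k: float = 0.5, r_ref: float = 2.0, displacement: float = 0.5,
                   mass: float = 250.0, box_edge: float = 50.0):
    """Two bonded sites stretched from equilibrium — an exactly solvable oscillator.

    Defaults give an oscillation period of ~2.7 ps, so the standard 0.004 ps
    step resolves a period with ~660 steps and the velocity-Verlet energy
    ripple stays below 1e-5 of the oscillation energy.
    """
    ff = _gas_forcefield(epsilon=0.0, mass=mass)
    pos = np.array([[0.0, 0.0, 0.0], [r_ref + displacement, 0.0, 0.0]])
    pos += box_edge / 2.0
    top = Topology(
        type_names=ff.type_names(), type_ids=np.zeros(2, int), positions=pos,
        molecule_ids=np.zeros(2, int), molecule_species=["dimer"],
        bonded_terms=[BondedTerm("bond", (0, 1), (k, r_ref))],
        box=np.full(3, box_edge),
    )
    return top, ff


def mie_fluid(n: int = 100, density: float = 0.005, seed: int = 0,
              epsilon: float = 0.3, r0: float = 4.0, mass: float = 40.0):
    """Neutral Mie (9-6) particles on a jittered lattice at a number density (Å⁻³)."""
    edge = (n / density) ** (1.0 / 3.0)
    side = int(np.ceil(n ** (1.0 / 3.0)))
    spacing = edge / side
    rng = np.random.default_rng(seed)
    cells = np.array([(i, j, k) for i in range(side)
                      for j in range(side) for k in range(side)])[:n]
    pos = (cells + 0.5) * spacing + rng.uniform(-0.1, 0.1, size=(n, 3))
    ff = _gas_forcefield(epsilon=epsilon, r0=r0, mass=mass)
    top = Topology(
        type_names=ff.type_names(), type_ids=np.zeros(n, int), positions=pos,
        molecule_ids=np.arange(n), molecule_species=["mie"] * n,
        box=np.full(3, edge),
    )
    return top, ff


def il_box(n_pairs: int = 64, seed: int = 0, target_density: float = 0.8):
    """Scaled-down [bmim][Cl] lattice box for the density protocol."""
    ff = default_forcefield()
    top = build_bmimcl(n_pairs, target_density=target_density, ff=ff, seed=seed)
    return top, ff


def mini_fiber(seed: int = 0, comp: CompositionSpec = MINI_FIBER_COMPOSITION,
               target_density: float = 1.0):
    """Scaled-down solvated fiber keeping the study composition ratios."""
    ff = default_forcefield()
    fiber = build_fiber(n_chains=comp.n_chains, n_units=comp.n_cellobiose_per_chain,
                        ff=ff)
    top = solvate(fiber, comp, ff=ff, seed=seed, target_density=target_density)
    return top, ff


def generate_fixture(spec: FixtureSpec):
    """Build (Topology, ForceField, SystemState) for a fixture spec."""
    kind = spec.kind
    if kind == "ideal_gas":
        top, ff = ideal_gas(spec.n or 1000, spec.box_edge or 30.0, spec.seed)
    elif kind == "nacl_lattice":
        top, ff = nacl_lattice(spec.n or 8, **spec.params)
    elif kind == "harmonic_dimer":
        top, ff = harmonic_dimer(**spec.params)
    elif kind == "mie_fluid":
        top, ff = mie_fluid(spec.n or 100, seed=spec.seed, **spec.params)
    elif kind == "il_box":
        top, ff = il_box(spec.n or 64, seed=spec.seed, **spec.params)
    else:
        top, ff = mini_fiber(seed=spec.seed, **spec.params)
    return top, ff, SystemState.from_topology(top, seed=spec.seed)
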