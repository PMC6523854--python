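"""Molecular-dynamics engine: velocity-Verlet, Nosé–Hoover NVT/NPT, rigid water.

Integrators advance a :class:`~miecg.system.SystemState` in place using a
bound :class:`~miecg.calculator.ForceEvaluator`.  The thermostat is a
single Nosé–Hoover chain with coupling time ``f`` (mass Q = N_f·k_B·T·f²);
the isotropic barostat is a Martyna–Tobias–Klein-style extended variable
with characteristic time ``f2`` (mass W = (N_f+3)·k_B·T·f2²), both damped
by the same thermostat.  SPC/E waters are kept rigid with SHAKE/RATTLE.

Degrees of freedom: ``3N − 3`` (centre-of-mass momentum removed) minus 3
per rigid water (three distance constraints each).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .calculator import ForceEvaluator
from .system import SystemState, Topology
from .units import ATM, KB, KE_CONV

#: acceleration conversion: a [Å·ps⁻²] = ACC · F[kcal·mol⁻¹·Å⁻¹] / m[g·mol⁻¹]
ACC = 1.0 / KE_CONV

# SPC/E rigid geometry (Å)
SPCE_OH = 1.0
SPCE_HH = 2.0 * SPCE_OH * np.sin(np.deg2rad(109.47 / 2.0))


class InstabilityError(RuntimeError):
    pass


class ConstraintError(RuntimeError):
    pass


@dataclass(frozen=True)
class EnsembleConfig:
    """Ensemble settings. Times in ps, T in K, P in atm, cutoff in Å."""

    kind: str = "NVT"
    T: float = 298.15
    P: float = 1.0
    f: float = 0.5       # thermostat coupling time
    f1: float = 0.5      # thermostat time in NPT
    f2: float = 3.0      # barostat time
    dt: float = 0.004
    cutoff: float = 15.0

    def __post_init__(self):
        if self.kind not in ("NVE", "NVT", "NPT"):
            raise ValueError(f"unknown ensemble kind {self.kind!r}")
        if self.dt <= 0 or self.f <= 0 or self.f1 <= 0 or self.f2 <= 0:
            raise ValueError("dt and coupling times must be positive")


@dataclass(frozen=True)
class ProtocolSpec:
    """Lattice → low-T equilibration → quench → production schedule.

    Spans in ps.  The quench is an instantaneous thermostat set-point change.
    """

    initial_T: float = 100.0
    equilibration_span: float = 800.0
    production_T: float = 298.15
    production_span: float = 100.0
    snapshot_stride: int = 50

    def __post_init__(self):
        if self.equilibration_span < 0 or self.production_span < 0:
            raise ValueError("spans must be non-negative")
        if self.snapshot_stride < 1:
            raise ValueError("snapshot stride must be >= 1")


# --- kinetic quantities -------------------------------------------------------


def count_dof(topology: Topology) -> int:
    """3N − 3 (COM) − 3 per rigid water."""
    n = topology.n_sites
    return 3 * n - 3 - 3 * len(topology.rigid_waters)


def kinetic_energy(velocities, masses) -> float:
    return 0.5 * KE_CONV * float(np.sum(masses * np.einsum("ij,ij->i", velocities, velocities)))


def kinetic_temperature(velocities, masses, dof: int) -> float:
    return 2.0 * kinetic_energy(velocities, masses) / (dof * KB)


def initialize_velocities(state: SystemState, masses, T: float, seed: int,
                          rigid_waters=None) -> None:
    """Maxwell–Boltzmann draw at T, net momentum zeroed, rescaled to T exactly."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB * T / (KE_CONV * masses))
    v = rng.standard_normal(state.positions.shape) * sigma[:, None]
    p = np.sum(masses[:, None] * v, axis=0)
    v -= p / masses.sum()
    if rigid_waters is not None and len(rigid_waters):
        rattle_velocities(state.positions, v, masses, rigid_waters)
    dof = count_dof(state.topology)
    if T > 0:
        t_now = kinetic_temperature(v, masses, dof)
        if t_now > 0:
            v *= np.sqrt(T / t_now)
    state.velocities = v


# --- rigid-water constraints (SHAKE / RATTLE) ---------------------------------


def _water_constraints(rigid_waters):
    """Constraint pair list (C,2) and target distances (C,) for SPC/E triplets."""
    w = np.asarray(rigid_waters, dtype=int).reshape(-1, 3)
    pairs = np.concatenate([w[:, [0, 1]], w[:, [0, 2]], w[:, [1, 2]]], axis=0)
    dists = np.concatenate([
        np.full(len(w), SPCE_OH), np.full(len(w), SPCE_OH), np.full(len(w), SPCE_HH)
    ])
    return pairs, dists


def shake_positions(pos_new, pos_old, masses, rigid_waters,
                    tol: float = 1e-8, max_iter: int = 500):
    """Iteratively restore water constraint distances in ``pos_new`` (in place).

    Returns the number of iterations used.  Constraint gradients are taken
    along the old (pre-step) bond vectors, the standard SHAKE linearisation.
    """
    pairs, dists = _water_constraints(rigid_waters)
    i, j = pairs[:, 0], pairs[:, 1]
    inv_mi = 1.0 / masses[i]
    inv_mj = 1.0 / masses[j]
    r_old = pos_old[i] - pos_old[j]
    d_sq = dists**2
    if _kernels.HAVE_NUMBA:
        it = _kernels.shake_kernel(
            pos_new, np.ascontiguousarray(r_old), i.astype(np.int64),
            j.astype(np.int64), inv_mi, inv_mj, d_sq,
            tol * float(np.maximum(d_sq, 1.0).max()), max_iter)
        if it < 0:
            raise ConstraintError(f"SHAKE did not converge in {max_iter} iterations")
        return it
    for it in range(max_iter):
        r_new = pos_new[i] - pos_new[j]
        diff = np.einsum("ij,ij->i", r_new, r_new) - d_sq
        if np.max(np.abs(diff)) < tol * np.maximum(d_sq, 1.0).max():
            return it
        denom = 2.0 * np.einsum("ij,ij->i", r_new, r_old) * (inv_mi + inv_mj)
        if np.any(np.abs(denom) < 1e-12):
            raise ConstraintError("degenerate constraint geometry in SHAKE")
        g = diff / denom
        corr = g[:, None] * r_old
        np.subtract.at(pos_new, i, corr * inv_mi[:, None])
        np.add.at(pos_new, j, corr * inv_mj[:, None])
    raise ConstraintError(f"SHAKE did not converge in {max_iter} iterations")


def rattle_velocities(positions, velocities, masses, rigid_waters,
                      tol: float = 1e-10, max_iter: int = 500):
    """Project velocities onto the constraint manifold (no net work)."""
    pairs, _ = _water_constraints(rigid_waters)
    i, j = pairs[:, 0], pairs[:, 1]
    inv_mi = 1.0 / masses[i]
    inv_mj = 1.0 / masses[j]
    if _kernels.HAVE_NUMBA:
        vtol = tol * max(1.0, float(np.max(np.abs(velocities))))
        it = _kernels.rattle_kernel(positions, velocities, i.astype(np.int64),
                                    j.astype(np.int64), inv_mi, inv_mj,
                                    vtol, max_iter)
        if it < 0:
            raise ConstraintError(f"RATTLE did not converge in {max_iter} iterations")
        return it
    r = positions[i] - positions[j]
    r_sq = np.einsum("ij,ij->i", r, r)
    for it in range(max_iter):
        v_rel = velocities[i] - velocities[j]
        dot = np.einsum("ij,ij->i", v_rel, r)
        if np.max(np.abs(dot) / np.sqrt(r_sq)) < tol * max(1.0, float(np.max(np.abs(velocities)))):
            return it
        g = dot / (r_sq * (inv_mi + inv_mj))
        corr = g[:, None] * r
        np.subtract.at(velocities, i, corr * inv_mi[:, None])
        np.add.at(velocities, j, corr * inv_mj[:, None])
    raise ConstraintError(f"RATTLE did not converge in {max_iter} iterations")


def constrain_water(state: SystemState, masses=None, ff=None,
                    tol: float = 1e-8) -> SystemState:
    """Restore rigid SPC/E geometry and remove constraint-violating velocity
    components for all flagged waters (in place; returns the state)."""
    top = state.topology
    if len(top.rigid_waters) == 0:
        return state
    if masses is None:
        if ff is None:
            from .forcefield import default_forcefield
            ff = default_forcefield()
        masses = top.masses(ff)
    shake_positions(state.positions, state.positions.copy(), masses,
                    top.rigid_waters, tol=tol)
    rattle_velocities(state.positions, state.velocities, masses, top.rigid_waters)
    return state


# --- integrator ---------------------------------------------------------------


@dataclass
class StepObservables:
    time: float
    temperature: float
    pressure_atm: float
    volume: float
    energy_terms: dict
    kinetic: float
    conserved: float

    @property
    def potential(self) -> float:
        return float(sum(self.energy_terms.values()))

    @property
    def total_energy(self) -> float:
        return self.potential + self.kinetic


class Integrator:
    """Velocity-Verlet core with optional Nosé–Hoover thermostat/barostat."""

    def __init__(self, state: SystemState, evaluator: ForceEvaluator,
                 cfg: EnsembleConfig):
        self.state = state
        self.ev = evaluator
        self.cfg = cfg
        self.masses = evaluator.masses
        self.dof = count_dof(state.topology)
        f_t = cfg.f1 if cfg.kind == "NPT" else cfg.f
        self.Q = self.dof * KB * max(cfg.T, 1.0) * f_t**2
        self.W = (self.dof + 3) * KB * max(cfg.T, 1.0) * cfg.f2**2
        self.P_ext = cfg.P * ATM
        self._has_waters = len(state.topology.rigid_waters) > 0
        self.report, self.forces, self.virial = evaluator.compute(state.positions, state.box)
        self._baro_work = 0.0

    # -- bookkeeping -----------------------------------------------------------

    def kinetic(self) -> float:
        return kinetic_energy(self.state.velocities, self.masses)

    def temperature(self) -> float:
        return kinetic_temperature(self.state.velocities, self.masses, self.dof)

    def pressure(self) -> float:
        """Instantaneous virial pressure, internal units."""
        return (2.0 * self.kinetic() + self.virial) / (3.0 * self.state.volume)

    def conserved_quantity(self) -> float:
        s = self.state
        e = self.report.total + self.kinetic()
        if self.cfg.kind == "NVT":
            e += 0.5 * self.Q * s.thermo_veta**2 + self.dof * KB * self.cfg.T * s.thermo_eta
        elif self.cfg.kind == "NPT":
            e += 0.5 * self.Q * s.thermo_veta**2 \
                + (self.dof + 1) * KB * self.cfg.T * s.thermo_eta \
                + 0.5 * self.W * s.baro_veps**2 + self.P_ext * s.volume
        return e

    def observables(self) -> StepObservables:
        return StepObservables(
            time=self.state.step * self.cfg.dt,
            temperature=self.temperature(),
            pressure_atm=self.pressure() / ATM,
            volume=self.state.volume,
            energy_terms=dict(self.report.terms),
            kinetic=self.kinetic(),
            conserved=self.conserved_quantity(),
        )

    # -- pieces ----------------------------------------------------------------

    def _check_forces(self):
        if not np.all(np.isfinite(self.forces)):
            bad = int(np.argwhere(~np.isfinite(self.forces))[0][0])
            raise InstabilityError(f"non-finite force on site {bad} at step {self.state.step}")

    def _thermostat_half(self, dt: float, couple_baro: bool):
        # the chain thermostats the particles and, in NPT, the barostat mode
        # (its kinetic energy W·vε² counts toward the target with one extra kBT)
        s = self.state
        k2 = 2.0 * self.kinetic()
        target = self.dof * KB * self.cfg.T
        if couple_baro:
            k2 += self.W * s.baro_veps**2
            target += KB * self.cfg.T
        s.thermo_veta += 0.25 * dt * (k2 - target) / self.Q
        scale = np.exp(-0.5 * dt * s.thermo_veta)
        s.velocities *= scale
        if couple_baro:
            s.baro_veps *= scale
        s.thermo_eta += 0.5 * dt * s.thermo_veta
        k2 *= scale * scale
        s.thermo_veta += 0.25 * dt * (k2 - target) / self.Q

    def _baro_force(self) -> float:
        k2 = 2.0 * self.kinetic()
        p_int = (k2 + self.virial) / (3.0 * self.state.volume)
        return (3.0 * self.state.volume * (p_int - self.P_ext) + (3.0 / self.dof) * k2) / self.W

    def _velocity_half(self, dt: float):
        self.state.velocities += 0.5 * dt * ACC * self.forces / self.masses[:, None]

    def _recompute(self):
        self.report, self.forces, self.virial = self.ev.compute(
            self.state.positions, self.state.box
        )
        self._check_forces()

    # -- steps -----------------------------------------------------------------

    def step_nve(self):
        s, dt = self.state, self.cfg.dt
        self._check_forces()
        self._velocity_half(dt)
        old = s.positions.copy()
        s.positions = s.positions + dt * s.velocities
        if self._has_waters:
            unconstrained = s.positions.copy()
            shake_positions(s.positions, old, self.masses, s.topology.rigid_waters)
            s.velocities += (s.positions - unconstrained) / dt
        self._recompute()
        self._velocity_half(dt)
        if self._has_waters:
            rattle_velocities(s.positions, s.velocities, self.masses, s.topology.rigid_waters)
        s.step += 1

    def step_nvt(self):
        dt = self.cfg.dt
        self._thermostat_half(dt, couple_baro=False)
        self.step_nve()
        self._thermostat_half(dt, couple_baro=False)

    def step_npt(self):
        s, dt = self.state, self.cfg.dt
        alpha = 1.0 + 3.0 / self.dof
        self._thermostat_half(dt, couple_baro=True)
        s.baro_veps += 0.5 * dt * self._baro_force()
        # velocity half with barostat drag
        s.velocities *= np.exp(-0.5 * dt * alpha * s.baro_veps)
        self._velocity_half(dt)
        # position/box update with cell scaling
        expand = np.exp(dt * s.baro_veps)
        old = s.positions.copy()
        s.positions = s.positions * expand + dt * s.velocities * np.exp(0.5 * dt * s.baro_veps)
        s.box = s.box * expand
        min_edge = float(np.min(s.box))
        if min_edge < 2.0:
            raise InstabilityError(f"box collapse (edge {min_edge:.3e} Å)")
        if self._has_waters:
            unconstrained = s.positions.copy()
            shake_positions(s.positions, old, self.masses, s.topology.rigid_waters)
            s.velocities += (s.positions - unconstrained) / dt
        self._recompute()
        self._velocity_half(dt)
        s.velocities *= np.exp(-0.5 * dt * alpha * s.baro_veps)
        if self._has_waters:
            rattle_velocities(s.positions, s.velocities, self.masses, s.topology.rigid_waters)
        s.baro_veps += 0.5 * dt * self._baro_force()
        self._thermostat_half(dt, couple_baro=True)
        s.step += 1

    def step(self):
        if self.cfg.kind == "NVE":
            self.step_nve()
        elif self.cfg.kind == "NVT":
            self.step_nvt()
        else:
            self.step_npt()

    def run(self, n_steps: int, stride: int = 0, callback=None) -> list:
        """Advance n_steps; collect StepObservables every ``stride`` steps."""
        out = []
        for i in range(n_steps):
            self.step()
            if stride and (i + 1) % stride == 0:
                obs = self.observables()
                out.append(obs)
                if callback is not None:
                    callback(self.state, obs)
        return out


# --- energy minimisation ------------------------------------------------------


def minimize(state: SystemState, evaluator: ForceEvaluator, max_steps: int = 200,
             max_disp: float = 0.2, ftol: float = 1.0) -> float:
    """Damped steepest descent to remove build overlaps before dynamics.

    Moves each site along the force, capped at ``max_disp`` Å per step, with
    backtracking when the energy rises.  Returns the final potential energy.
    """
    masses = evaluator.masses
    rigid = state.topology.rigid_waters
    report, forces, _ = evaluator.compute(state.positions, state.box)
    energy = report.total
    gamma = 1e-4
    for _ in range(max_steps):
        fmax = float(np.max(np.abs(forces))) if len(forces) else 0.0
        if fmax < ftol:
            break
        step_vec = gamma * forces
        norm = np.linalg.norm(step_vec, axis=1)
        over = norm > max_disp
        if np.any(over):
            step_vec[over] *= (max_disp / norm[over])[:, None]
        trial = state.positions + step_vec
        if len(rigid):
            shake_positions(trial, state.positions.copy(), masses, rigid)
        new_report, new_forces, _ = evaluator.compute(trial, state.box)
        if new_report.total <= energy:
            state.positions = trial
            energy = new_report.total
            forces = new_forces
            report = new_report
            gamma *= 1.2
        else:
            gamma *= 0.5
            if gamma < 1e-10:
                break
    return energy


# --- protocol runner ----------------------------------------------------------


@dataclass
class Trajectory:
    """In-memory trajectory: frames (positions+box) and observable records."""

    frames: list = field(default_factory=list)  # list of (positions, box) copies
    records: list = field(default_factory=list)  # list of StepObservables
    stage_labels: list = field(default_factory=list)

    def volumes(self) -> np.ndarray:
        return np.array([r.volume for r in self.records])

    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records])


def run_protocol(topology: Topology, ff, protocol: ProtocolSpec,
                 ensemble: EnsembleConfig, seed: int = 0,
                 ewald=None, minimize_steps: int = 200,
                 frame_callback=None) -> Trajectory:
    """Lattice start → equilibrate at ``initial_T`` (NVT) → quench → production.

    Equilibration runs NVT at the initial temperature with the box fixed at
    the build volume; the quench is an instantaneous set-point change to the
    production temperature, after which the requested ensemble runs for the
    production span.
    """
    state = SystemState.from_topology(topology, seed=seed)
    ev = ForceEvaluator(topology, ff, cutoff=ensemble.cutoff, ewald=ewald)
    if minimize_steps:
        minimize(state, ev, max_steps=minimize_steps)
    initialize_velocities(state, ev.masses, protocol.initial_T, seed,
                          rigid_waters=topology.rigid_waters)
    traj = Trajectory()

    def _collect(stage):
        def cb(st, obs):
            traj.frames.append((st.positions.copy(), st.box.copy()))
            traj.records.append(obs)
            traj.stage_labels.append(stage)
            if frame_callback is not None:
                frame_callback(st, obs, stage)
        return cb

    dt = ensemble.dt
    n_equil = int(round(protocol.equilibration_span / dt))
    if n_equil:
        eq_cfg = EnsembleConfig(kind="NVT", T=protocol.initial_T, P=ensemble.P,
                                f=ensemble.f, f1=ensemble.f1, f2=ensemble.f2,
                                dt=dt, cutoff=ensemble.cutoff)
        integ = Integrator(state, ev, eq_cfg)
        integ.run(n_equil, stride=protocol.snapshot_stride, callback=_collect("equilibration"))

    n_prod = int(round(protocol.production_span / dt))
    if n_prod:
        prod_cfg = EnsembleConfig(kind=ensemble.kind, T=protocol.production_T,
                                  P=ensemble.P, f=ensemble.f, f1=ensemble.f1,
                                  f2=ensemble.f2, dt=dt, cutoff=ensemble.cutoff)
        # fresh thermostat state at the quench
        state.thermo_eta = 0.0
        state.thermo_veta = 0.0
        state.baro_veps = 0.0
        integ = Integrator(state, ev, prod_cfg)
        integ.run(n_prod, stride=protocol.snapshot_stride, callback=_collect("production"))
    return traj
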