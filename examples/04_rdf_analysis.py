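"""Radial distribution functions: normalisation checks and a quick IL run.

First verifies the g(r) machinery on an ideal gas (g must be 1 everywhere),
then runs a short NVT trajectory of a small [bmim][Cl] box and prints the
anion–cation first-shell structure: the chloride coordinates the charged
imidazolium ring beads (I1/I2) at contact, while the neutral butyl tail (CT)
shows a weaker, more diffuse correlation.
"""

import numpy as np

from miecg import (
    EnsembleConfig,
    EwaldConfig,
    ForceEvaluator,
    Integrator,
    SystemState,
    build_bmimcl,
    default_forcefield,
    initialize_velocities,
    minimize,
    rdf,
)
from miecg.fixtures import ideal_gas

# --- ideal-gas limit: g(r) = 1 ---
frames = []
for seed in range(6):
    top_gas, _ = ideal_gas(800, box_edge=30.0, seed=seed)
    frames.append((top_gas.positions, top_gas.box))
res = rdf(frames, top_gas, "X", "X", dr=0.25)
sel = (res.r > 3) & (res.r < 14)
print(f"ideal gas: <g> = {res.g[sel].mean():.3f} ± {res.g[sel].std():.3f} "
      f"(exactly 1 in the infinite-sampling limit)")

# --- short ionic-liquid trajectory ---
ff = default_forcefield()
top = build_bmimcl(24, target_density=0.8, ff=ff, seed=7)
cut = 8.0
ev = ForceEvaluator(top, ff, cutoff=cut,
                    ewald=EwaldConfig(alpha=0.4, kmax=(8, 8, 8), real_cutoff=cut))
state = SystemState.from_topology(top, seed=7)
minimize(state, ev, max_steps=100)
initialize_velocities(state, ev.masses, 400.0, 7)
integ = Integrator(state, ev, EnsembleConfig(kind="NVT", T=400.0, dt=0.004,
                                             cutoff=cut))
integ.run(2500)  # 10 ps equilibration
il_frames = []
for _ in range(20):  # 8 ps sampled every 0.4 ps
    integ.run(100)
    il_frames.append((state.positions.copy(), state.box.copy()))

print(f"\n[bmim][Cl] at 400 K ({top.n_sites} sites, 8 ps sampling):")
for site in ("I1", "I2", "CT"):
    res = rdf(il_frames, top, "CI", site, dr=0.25)
    r_pk, g_pk = res.first_peak(r_min=3.0, r_max=6.5)
    print(f"  Cl–{site}: first-shell peak g = {g_pk:.2f} at r = {r_pk:.2f} Å")
print("\nThe charged ring beads bind the anion at contact; the neutral tail "
      "correlates only weakly — the ionic cage structure of the liquid.")
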