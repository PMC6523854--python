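"""Mie pair potential: well depth, well position, mixing rules.

Builds the packaged [bmim][Cl] force field, evaluates the Mie potential for
a few site pairs and prints the well parameters.  The printed energies are
in kcal/mol and distances in Å: U(r0) equals −ε by construction, and the
cross-interaction parameters come from Lorentz–Berthelot mixing.
"""

import numpy as np

from miecg import default_forcefield, mie_energy, mie_energy_force, mix_params

ff = default_forcefield()

print("site    epsilon   n   m     r0      sigma")
for name in ("I1", "I2", "I3", "CT", "CI"):
    p = ff.site_types[name].self_params
    print(f"{name:4s}  {p.epsilon:8.3f}  {p.n:2.0f}  {p.m:2.0f}  {p.r0:6.3f}  {p.sigma:6.3f}")

p = ff.site_types["I1"].self_params
u_min, f_min = mie_energy_force(p.r0, p)
print(f"\nI1–I1 at its minimum r0={p.r0} Å: U = {u_min:.4f} kcal/mol "
      f"(= −ε), force = {f_min:.2e}")
print(f"I1–I1 compressed to 4.0 Å: U = {mie_energy(4.0, p):+.4f} kcal/mol (repulsive)")

cross = mix_params(ff.site_types["I1"], ff.site_types["CT"])
print(f"\nI1–CT cross interaction (Lorentz–Berthelot): "
      f"ε = {cross.epsilon:.4f} = sqrt(0.375·0.469), σ = {cross.sigma:.4f} Å")

r = np.array([4.0, 4.693, 6.0, 10.0, 15.0])
print("\nr [Å]      U(r) I1–I1 [kcal/mol]")
for ri, ui in zip(r, mie_energy(r, p)):
    print(f"{ri:6.3f}    {ui:+.5f}")
print("\nThe potential crosses zero at sigma, reaches −ε at r0 and decays as r⁻⁶.")
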