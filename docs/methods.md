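# Methods

`miecg` is a coarse-grained (CG) molecular-dynamics code for mixtures of the
ionic liquid 1-butyl-3-methylimidazolium chloride ([bmim][Cl]), cellulose and
water. This note records the model, the numerical choices, and what the
desk-scale tests do and do not demonstrate.

## Model

### Non-bonded interactions

Site–site van der Waals interactions use the Mie (generalised Lennard-Jones)
potential

    U(r) = ε/(n−m) · [ m (r0/r)^n − n (r0/r)^m ]

with well depth ε (kcal/mol), well position r0 (Å), repulsive exponent n and
attractive exponent m. The collision diameter obeys
`r0 = σ (n/m)^(1/(n−m))`. The packaged registry
(`miecg/data/bmimcl_cg.yaml`) carries the published five-site [bmim][Cl]
parameter set — two imidazolium ring beads (I1, I2), a methyl bead (I3), a
butyl bead (CT), all 9-6, and a 12-6 chloride (CI). The parameter table
prints exponent columns in the order (repulsive, attractive); the
accompanying prose swaps the two names, and this package follows the table.

Unlike pairs use Lorentz–Berthelot mixing (arithmetic σ, geometric ε). The
mixing rule does not define cross exponents; the default here is the
arithmetic mean rounded to the nearest integer, with the repulsive exponent
floored at m+1 (`mixing.exponent: arithmetic` in the registry; `fixed` takes
the first site's exponents instead).

Electrostatics are Coulombic with Ewald summation (erfc-screened real-space
part on the pair list, reciprocal sum bounded by integer `kmax`, self term,
and erf corrections for excluded intramolecular pairs). The documented
defaults are α = 0.18520 Å⁻¹ and kmax = (8, 8, 16), appropriate for the
full-size (~100 Å) boxes with the 15 Å cutoff; smaller boxes need a larger α
and rescaled kmax, and the scaled-down runs in the tests use α = 0.32 Å⁻¹,
kmax = (8,8,8) with a 10 Å cutoff.

**Charges are a model choice, not a published value.** The cation's +1 is
placed on the two ring beads (+0.5 each; I3 and CT neutral) and −1 on the
chloride. For cellulose, the six beads per cellobiose (C11, C14, C16 on
glucose 1; C21, C24, C26 on glucose 2; beads on the C1, C4, C6 carbon
regions) carry small partial charges that act as a CG proxy for
hydrogen-bond donation: +0.25 on the C6 hydroxymethyl beads (C16/C26, the
most reactive hydroxyl), +0.15 on C11/C24 (less reactive hydroxyls), and
−0.40 on the hydroxyl-free C14/C21 so each chain is neutral. The cellulose
Mie parameters are likewise synthetic model-construction values (marked so
in the registry). These choices produce the qualitative anion–cellulose
structure the model is meant to show — chloride correlating most strongly
with C16/C26, weakly with C11/C24, negligibly with the backbone beads — and
they are exactly the kind of quantity a user would re-parameterise for
quantitative work.

Water is rigid SPC/E: O–H 1.0 Å, H–O–H 109.47°, q(O) = −0.8476,
q(H) = +0.4238, 12-6 oxygen site (ε = 0.1553 kcal/mol, σ = 3.166 Å), held
rigid by SHAKE/RATTLE rather than bonded terms.

### Bonded terms and molecular templates

Bonds and bends are harmonic; dihedrals are a single cosine term
`k(1 + cos(pφ − δ))`. Force constants are registry defaults (60 kcal/mol/Å²
bonds, 15 kcal/mol/rad² bends, 0.8 kcal/mol dihedrals — soft, CG-scale
values); the *reference geometry* (lengths, angles, phases) is derived from
the template coordinates in the registry, so every freshly built molecule
sits exactly at its bonded minimum. The cation is the chain I3–I1–I2–CT
(3 bonds, 2 bends, 1 dihedral).

The cellobiose repeat unit owns a 7-bond / 4-bend / 8-dihedral template in
which the terms spanning the glycosidic linkage to the *next* unit belong to
the preceding unit; a terminal unit drops them (1 bond, 1 bend, 5
dihedrals), so an n-unit chain carries 7n−1 / 4n−1 / 8n−5 terms. The six
cellulose site types give C(6,2)+6 = 21 distinct nonbonded pair
combinations. The C16 bead is anchored to both C14 and C11 (the C6 arm sits
between them); C26 is anchored to C24 with a bend to C21 — the β-linkage
alternation makes the two glucoses inequivalent in the CG geometry.

### Exclusions and cutoff smoothing

Intramolecular 1-2 and 1-3 pairs are excluded from Mie and real-space
Coulomb sums (their reciprocal-space image is subtracted analytically); 1-4
pairs are included with a configurable scale (default 1.0).

The Mie term is smoothly switched to zero with a quintic blend over the last
1 Å before the cutoff. Plain truncation leaves an energy jump at every pair-
list crossing and produced NVE drifts of order 1e-2 (relative, 1e5 steps);
with the switch both energy and force are continuous and the secular drift
falls to ~2e-6. This is a deliberate deviation from bare truncation, made so
that the integrator meets a microcanonical conservation contract.

## Dynamics

Velocity-Verlet at dt = 0.004 ps throughout. Temperature control is a
single Nosé–Hoover chain with coupling time f (mass Q = N_f·k_B·T·f²,
N_f = 3N − 3 − 3·n_water); pressure control is an isotropic
Martyna–Tobias–Klein-style barostat with characteristic time f2
(mass W = (N_f+3)·k_B·T·f2²). Defaults: f = f1 = 0.5 ps, f2 = 3.0 ps,
P = 1 atm. The same thermostat chain also thermostats the barostat velocity
(its kinetic energy plus one extra k_B·T in the chain's target); full MTK
prescribes a separate chain for the cell — the shared chain is a documented
simplification that reproduces the ideal-gas equation of state ⟨V⟩ = NkT/P
to a few tenths of a percent. SHAKE restores water geometry to 1e-8 Å after
every position update and RATTLE projects constraint-violating velocity
components.

The simulation protocol follows the study design: build on a lattice,
steepest-descent minimise (overlap relief only), draw Maxwell–Boltzmann
velocities, equilibrate by NVT at 100 K (800 ps by default; minutes-scale
runs use shorter spans), then quench instantaneously to the production
temperature and run the production ensemble (NPT for densities). The
equilibration ensemble is not specified in the source description; NVT at
the build volume is this package's choice, with the barostat engaging only
after the quench.

Initial velocities are seeded Maxwell–Boltzmann draws with the net momentum
removed and a rescale to the exact target temperature. All builders and the
protocol runner are bit-reproducible given (spec, seed).

## Analysis

* **Equilibration detection**: scan candidate start indices; accept the
  first where the two halves of the remaining series have means within one
  pooled standard error (threshold configurable). A series trending to the
  end is *flagged*, not raised.
* **Density**: ρ = M_total/⟨V⟩ over the post-equilibration window, error
  propagated from std(V) (σ_ρ = ρ·σ_V/⟨V⟩).
* **MABD** (mean absolute percentage deviation): 100·|ρ_md − ρ_ref|/ρ_md,
  i.e. the *simulated* value in the denominator — deliberately asymmetric,
  matching the convention recoverable from the published density table
  (e.g. 100·|1.157−1.067|/1.157 = 7.78 against the printed 7.77; the
  remaining ±0.01 comes from the table's rounding). Vector input averages
  per-temperature values (mean 7.55% over the four printed rows, reported
  in the source as 7.5%).
* **RDF**: standard pair-count normalisation by the ideal-gas shell
  expectation, k-d-tree pair search, unordered pairs counted once,
  same-type normalisation N(N−1)/2.

## Scaled-down study conditions

Full-scale reproduction of the density table needs 256 ion pairs and
80–160 ns per temperature; desk-scale runs here use:

* **Density**: 64 pairs, lattice at 0.9 g/cm³, 10 ps at 100 K, then 120 ps
  NPT at 298.15 K with cutoff 10 Å (the liquid box is ~25 Å across, so the
  full-size 15 Å cutoff cannot satisfy the minimum-image bound). The volume
  plateaus within ~60 ps at ρ ≈ 1.21 g/cm³, within 4% of the full-scale
  published 1.169 g/cm³ — finite-size effects and the synthetic bonded
  constants account for the offset.
* **Solvated fiber**: the mini fixture (4 chains × 10 cellobiose, 200 IL
  pairs, 270 waters — the study's water:IL ratio at ~1/14 scale) runs 50 ps
  NVT; the chloride–cellulose RDF first-peak ordering
  (C16/C26 > C11/C24 > backbone) emerges from the charge model within that
  span. Peak *heights* at this size are not converged; only the ordering is
  meaningful.
* **Thermostat/barostat contracts** are verified on 100-site Mie fluids
  (200 ps NVT within 2% of the set temperature; supercritical NPT pressure
  within block-statistical error of the set point).

What these runs do **not** show: quantitative transferability of the
synthetic cellulose parameters, long-time (ns–scale) relaxation of the
fiber, surface tension or transport coefficients (outside this model's
reliable scope), or the 80 ns volume-equilibration behaviour of the
full-size system.

## Numerical choices and degenerate inputs

* Pair singularity guard: interacting sites closer than 1e-6 Å raise an
  error rather than returning infinities.
* Cutoff must not exceed half the shortest box edge (checked everywhere);
  the Verlet list (skin 2 Å) rebuilds when any site moves more than skin/2
  or the box changes by more than skin/4.
* Builders resolve random-orientation overlaps by re-rotating offending
  molecules (deterministic, seeded) and guarantee a minimum site separation
  of 0.5 Å; genuinely unplaceable requests raise a packing error.
* The reciprocal-space kernel (and SHAKE/RATTLE) run through numba when it
  is available, with pure-NumPy fallbacks; both paths agree to 1e-12 and
  are covered by the same tests.
* Ideal-gas NPT fixtures start at the equilibrium volume: with no
  interparticle coupling, an initial barostat oscillation is undamped and
  would persist indefinitely (a property of extended-system dynamics, not a
  bug); interacting systems damp it naturally.

## Known limitations

* The barostat is isotropic and the cell orthorhombic; no anisotropic or
  triclinic coupling.
* Exponent mixing for unlike Mie pairs is a convention, not physics; both
  provided rules are documented and configurable.
* Charges and cellulose parameters are model defaults (see above); absolute
  densities and peak heights inherit that uncertainty.
* Single-threaded; system sizes beyond ~3×10⁴ sites are impractical.
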