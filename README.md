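# miecg

Coarse-grained molecular dynamics of cellulose dissolving in the ionic
liquid 1-butyl-3-methylimidazolium chloride ([bmim][Cl]) with water.

Ionic liquids dissolve cellulose by letting the anion hydrogen-bond to the
glucan hydroxyl groups, out-competing the inter-chain hydrogen bonds that
hold fibers together. Studying that mesoscale process with all-atom force
fields is prohibitively slow, so this package implements a coarse-grained
model: five Mie-potential beads per [bmim][Cl] ion pair (ring beads I1/I2,
methyl I3, butyl CT, chloride CI), six beads per cellobiose repeat unit
(C11, C14, C16 / C21, C24, C26 — the C1, C4, C6 regions of the two
glucoses), and rigid SPC/E water. It is aimed at researchers who want a
small, fully inspectable simulator for IL–cellulose systems: every energy
term, integrator and analysis step is plain Python/NumPy (with optional
numba acceleration) and is unit-tested against independent oracles.

## The model

Van der Waals interactions use the Mie potential

    U(r) = ε/(n−m) · [ m (r0/r)^n − n (r0/r)^m ],
    r0 = σ (n/m)^(1/(n−m)),

with the published five-site [bmim][Cl] parameter set packaged as the
default registry and Lorentz–Berthelot mixing for unlike pairs.
Electrostatics are Ewald-summed point charges; dynamics are velocity-Verlet
(dt = 0.004 ps) under NVE, Nosé–Hoover NVT (f = 0.5 ps) or Nosé–Hoover NPT
(f1 = 0.5 ps, f2 = 3.0 ps), with SHAKE/RATTLE keeping water rigid. The
simulation protocol mirrors the study design: lattice start, NVT
equilibration at 100 K, instantaneous quench, NPT production. Analysis
covers equilibration detection, densities with uncertainties, the mean
absolute percentage deviation (MABD) against reference densities, and
site–site radial distribution functions g(r). See `docs/methods.md` for
assumptions and numerical choices.

## Worked example

```bash
python examples/02_build_systems.py
```

prints, among other audits:

```
[bmim][Cl] box: 256 ion pairs -> 1280 sites (4-site cation + 1-site chloride), box edge 40.7 Å
cellulose chain: 10 cellobiose units -> 60 sites
  bonded terms: 69 bonds, 39 bends, 75 dihedrals (per-unit template 7/4/8, ...)
solvated system: fiber + 2826 IL pairs + 3809 waters -> 27717 sites
  water mass fraction:        10.1 % w/w
  cellulose in (cellulose+IL): 19.1 % w/w
```

i.e. the 36-chain fiber solvated with 2826 ion pairs and 3809 waters
reproduces the nominal 10% w/w water mixture, and a 10-unit chain carries
the 7-bond/4-bend/8-dihedral per-cellobiose bonded template (terminal unit
dropping the linkage-spanning terms). `examples/01_mie_potential.py` prints
the pair-potential table (U(r0) = −ε exactly), and
`examples/03_density_protocol.py` runs a minutes-scale NPT density
prediction with equilibration detection.

The same workflows are scriptable from the shell:

```bash
miecg run --config run.yaml --seed 7 --out out/
miecg analyze density --trajectory out/trajectory.extxyz --topology out/topology.json --reference 1.082
miecg validate        # built-in physics oracle checks
```

Configs are YAML with explicit units (`dt: "0.004 ps"`); every run writes a
reproducibility manifest (config hash, seed, versions).

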