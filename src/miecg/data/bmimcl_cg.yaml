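# Coarse-grained force-field registry: [bmim][Cl] ionic liquid + cellulose + SPC/E water.
#
# Site-site Mie parameters for the ionic liquid (I1, I2 imidazolium ring halves,
# I3 methyl, CT butyl tail, CI chloride) are the published CG parameter set for
# this five-site model: epsilon in kcal/mol, r0 (well position) in Å, with
# repulsive exponent n and attractive exponent m.
#
# Charges are NOT part of the published table.  The defaults below put the
# cation's +1 on the two ring beads and -1 on the chloride; they are a
# documented model choice and can be overridden in a user registry file.
#
# The six-site cellobiose bead parameters (C11, C14, C16 / C21, C24, C26:
# beads centred on the C1, C4 and C6 regions of each glucose) are SYNTHETIC
# model-construction values chosen for this package: the small positive
# charges on the hydroxyl-bearing beads (largest on C16/C26, whose C6
# hydroxyl is the most reactive; smaller on C11/C24) act as a coarse-grained
# proxy for hydrogen-bond donation toward the chloride anion, balanced by
# negative charges on the hydroxyl-free backbone beads so every chain is
# neutral.
#
# SPC/E water: rigid geometry (O-H 1.0 Å, H-O-H 109.47 deg) handled by
# constraints; 12-6 interaction on oxygen only (sigma 3.166 Å -> r0 below),
# q(O) = -0.8476, q(H) = +0.4238.

mixing:
  exponent: arithmetic   # unlike-pair exponents: rounded arithmetic mean

exclusions:
  exclude12: true
  exclude13: true
  scale14: 1.0

site_types:
  I1: {mass: 33.540, charge:  0.50, epsilon: 0.375, n: 9,  m: 6, r0: 4.693}
  I2: {mass: 33.531, charge:  0.50, epsilon: 0.345, n: 9,  m: 6, r0: 4.693}
  I3: {mass: 15.035, charge:  0.00, epsilon: 0.199, n: 9,  m: 6, r0: 4.120}
  CT: {mass: 57.116, charge:  0.00, epsilon: 0.469, n: 9,  m: 6, r0: 5.249}
  CI: {mass: 35.453, charge: -1.00, epsilon: 0.148, n: 12, m: 6, r0: 4.232}
  OW: {mass: 15.9994, charge: -0.8476, epsilon: 0.1553, n: 12, m: 6, r0: 3.553714844947475}
  HW: {mass: 1.008, charge: 0.4238, epsilon: 0.0, n: 12, m: 6, r0: 1.0}
  # --- synthetic cellulose bead parameters (see header note) ---
  C11: {mass: 57.05, charge:  0.15, epsilon: 0.35, n: 9, m: 6, r0: 5.00}
  C14: {mass: 55.05, charge: -0.40, epsilon: 0.35, n: 9, m: 6, r0: 5.00}
  C16: {mass: 50.04, charge:  0.25, epsilon: 0.40, n: 9, m: 6, r0: 4.40}
  C21: {mass: 57.05, charge:  0.15, epsilon: 0.35, n: 9, m: 6, r0: 5.00}
  C24: {mass: 55.05, charge: -0.40, epsilon: 0.35, n: 9, m: 6, r0: 5.00}
  C26: {mass: 50.04, charge:  0.25, epsilon: 0.40, n: 9, m: 6, r0: 4.40}

molecules:
  # Template coordinates (Å) define the build geometry; bonded reference
  # lengths/angles/phases are derived from these coordinates at build time so
  # every freshly built molecule sits at its bonded-energy minimum.
  bmim:
    sites: [I1, I2, I3, CT]
    coords:
      - [0.0, 0.0, 0.0]     # I1 ring bead (methyl side)
      - [2.2, 0.0, 0.0]     # I2 ring bead (butyl side)
      - [-2.3, 0.8, 0.0]    # I3 methyl
      - [4.4, 1.5, 0.6]     # CT butyl centroid
    bonds: [[2, 0], [0, 1], [1, 3]]
    bends: [[2, 0, 1], [0, 1, 3]]
    dihedrals: [[2, 0, 1, 3]]
    bond_k: 60.0        # kcal/mol/Å^2
    bend_k: 15.0        # kcal/mol/rad^2
    dihedral_k: 0.8     # kcal/mol
    dihedral_mult: 1
  chloride:
    sites: [CI]
    coords: [[0.0, 0.0, 0.0]]
  water:
    sites: [OW, HW, HW]
    coords:
      - [0.0, 0.0, 0.0]
      - [0.8164904309201172, 0.5773589665155304, 0.0]
      - [-0.8164904309201172, 0.5773589665155304, 0.0]
    rigid: true
  cellulose:
    # one cellobiose repeat unit; site order [C11, C14, C16, C21, C24, C26]
    unit_sites: [C11, C14, C16, C21, C24, C26]
    unit_coords:
      - [2.9, 0.6, 0.0]     # C11 glucose-1 C1
      - [0.0, 0.0, 0.0]     # C14 glucose-1 C4
      - [1.6, 1.8, 1.2]     # C16 glucose-1 C6 (hydroxymethyl)
      - [8.1, 0.6, 0.0]     # C21 glucose-2 C1
      - [5.2, 0.0, 0.0]     # C24 glucose-2 C4
      - [6.8, -1.5, -1.2]   # C26 glucose-2 C6 (hydroxymethyl)
    period: 10.4            # repeat translation along the chain axis, Å
    bond_k: 60.0
    bend_k: 15.0
    dihedral_k: 0.8
    dihedral_mult: 1

# Species molar masses implied by the site masses above:
#   water 18.015, [bmim][Cl] ion pair 174.675, cellobiose repeat 324.28 g/mol
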