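"""Builders for the study systems: ionic-liquid boxes, cellulose chains,
fibers, and solvated mixtures.

Conventions
-----------
* Molecule geometries come from the force-field registry templates; bonded
  reference lengths, angles and dihedral phases are derived from those
  template coordinates, so a freshly built molecule sits at the minimum of
  its bonded energy.
* Every build is a pure function of (arguments, seed): the same seed gives a
  bit-identical topology.
* Cellulose: six beads per cellobiose repeat unit (C11, C14, C16 / C21, C24,
  C26, beads on the C1, C4, C6 regions of the two glucoses).  The per-unit
  bonded template is 7 bonds, 4 bends and 8 dihedrals, where each unit owns
  the terms that span the glycosidic linkage to the *next* unit; terminal
  units simply drop those linkage-spanning terms, so an n-unit chain carries
  7n−1 bonds, 4n−1 bends and 8n−5 dihedrals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .forcefield import BondedTerm, ForceField, default_forcefield
from .system import Topology, TopologyError
from .units import AVOG_CM3

#: chloride offset from the cation template origin when a pair is placed as one unit
_PAIR_CL_OFFSET = np.array([0.8, -4.3, 0.0])

#: species aliases for composition queries
SPECIES_GROUPS = {
    "il": ("bmim", "chloride"),
    "water": ("water",),
    "cellulose": ("cellulose",),
    "bmim": ("bmim",),
    "chloride": ("chloride",),
}


class PackingError(RuntimeError):
    """Molecules could not be placed without overlap in the requested box."""


@dataclass(frozen=True)
class CompositionSpec:
    """Solvated-system composition: counts of IL pairs, waters, chains, units."""

    n_il_pairs: int = 0
    n_water: int = 0
    n_chains: int = 0
    n_cellobiose_per_chain: int = 0

    def __post_init__(self):
        if min(self.n_il_pairs, self.n_water, self.n_chains,
               self.n_cellobiose_per_chain) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_il_pairs + self.n_water + self.n_chains == 0:
            raise ValueError("at least one species must be present")


# --- geometry helpers ---------------------------------------------------------


def _dist(a, b):
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def _angle(a, b, c):
    u = np.asarray(a) - np.asarray(b)
    v = np.asarray(c) - np.asarray(b)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedral(a, b, c, d):
    b1 = np.asarray(b) - np.asarray(a)
    b2 = np.asarray(c) - np.asarray(b)
    b3 = np.asarray(d) - np.asarray(c)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2)
    return float(np.arctan2(y, x))


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix from a normalised quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# --- molecule templates -------------------------------------------------------


class _Unit:
    """A rigid placement unit: one or more molecules placed together."""

    def __init__(self, site_types, coords, molecules, terms, rigid_water_local):
        self.site_types = list(site_types)          # type-name labels
        self.coords = np.asarray(coords, float)     # (k,3) template coordinates
        self.molecules = list(molecules)            # (species, local site indices)
        self.terms = list(terms)                    # BondedTerm with local indices
        self.rigid_water_local = rigid_water_local  # list of (o,h,h) local triplets

    @property
    def n_sites(self):
        return len(self.coords)


def _template_terms(mol: dict, coords: np.ndarray) -> list:
    """Bonded terms for one template molecule, reference geometry from coords."""
    terms = []
    bond_k = float(mol.get("bond_k", 60.0))
    bend_k = float(mol.get("bend_k", 15.0))
    dih_k = float(mol.get("dihedral_k", 0.8))
    mult = int(mol.get("dihedral_mult", 1))
    for (i, j) in mol.get("bonds", []):
        terms.append(BondedTerm("bond", (i, j), (bond_k, _dist(coords[i], coords[j]))))
    for (i, j, k) in mol.get("bends", []):
        terms.append(BondedTerm("bend", (i, j, k),
                                (bend_k, _angle(coords[i], coords[j], coords[k]))))
    for (i, j, k, l) in mol.get("dihedrals", []):
        phi = _dihedral(coords[i], coords[j], coords[k], coords[l])
        # U = k(1+cos(pφ−δ)) has its minimum at pφ−δ = π
        terms.append(BondedTerm("dihedral", (i, j, k, l), (dih_k, float(mult),
                                                           mult * phi - np.pi)))
    return terms


def _simple_unit(ff: ForceField, species: str) -> _Unit:
    mol = ff.molecules[species]
    coords = np.asarray(mol["coords"], float)
    coords = coords - coords.mean(axis=0)
    rigid = [(0, 1, 2)] if mol.get("rigid") else []
    return _Unit(mol["sites"], coords, [(species, list(range(len(coords))))],
                 [] if mol.get("rigid") else _template_terms(mol, coords), rigid)


def _il_pair_unit(ff: ForceField) -> _Unit:
    cat = ff.molecules["bmim"]
    coords = np.asarray(cat["coords"], float)
    coords_all = np.vstack([coords, _PAIR_CL_OFFSET[None, :]])
    coords_all = coords_all - coords_all.mean(axis=0)
    site_types = list(cat["sites"]) + list(ff.molecules["chloride"]["sites"])
    terms = _template_terms(cat, coords_all[: len(coords)])
    mols = [("bmim", list(range(len(coords)))), ("chloride", [len(coords)])]
    return _Unit(site_types, coords_all, mols, terms, [])


# --- cellulose ----------------------------------------------------------------

# local site order within a repeat unit
_CELL_ORDER = ("C11", "C14", "C16", "C21", "C24", "C26")
_C11, _C14, _C16, _C21, _C24, _C26 = range(6)

# per-unit bonded template: local indices; +6 refers to the next unit.
_CELL_BONDS = [
    (_C14, _C11), (_C11, _C24), (_C24, _C21),       # backbone
    (_C14, _C16), (_C11, _C16), (_C24, _C26),       # hydroxymethyl anchors
    (_C21, _C14 + 6),                               # glycosidic linkage (spans)
]
_CELL_BENDS = [
    (_C14, _C11, _C24), (_C11, _C24, _C21), (_C26, _C24, _C21),
    (_C24, _C21, _C14 + 6),                         # spans
]
_CELL_DIHEDRALS = [
    (_C14, _C11, _C24, _C21), (_C16, _C14, _C11, _C24), (_C16, _C11, _C24, _C21),
    (_C11, _C24, _C21, _C14 + 6), (_C24, _C21, _C14 + 6, _C11 + 6),
    (_C26, _C24, _C21, _C14 + 6), (_C24, _C21, _C14 + 6, _C16 + 6),
    (_C21, _C14 + 6, _C11 + 6, _C24 + 6),           # all five above span the linkage
]

CELLULOSE_UNIT_TEMPLATE_COUNTS = {
    "bond": len(_CELL_BONDS), "bend": len(_CELL_BENDS), "dihedral": len(_CELL_DIHEDRALS)
}


def cellulose_pair_combinations() -> int:
    """Unique unordered type-pair combinations among the 6 cellulose site types."""
    t = len(_CELL_ORDER)
    return t * (t - 1) // 2 + t


def _cellulose_chain_unit(ff: ForceField, n_units: int) -> _Unit:
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    mol = ff.molecules["cellulose"]
    unit_coords = np.asarray(mol["unit_coords"], float)
    period = float(mol["period"])
    coords = np.vstack([unit_coords + np.array([u * period, 0.0, 0.0])
                        for u in range(n_units)])
    # extended coordinates (one ghost unit) to measure linkage reference geometry
    ext = np.vstack([coords, unit_coords + np.array([n_units * period, 0.0, 0.0])])
    bond_k = float(mol.get("bond_k", 60.0))
    bend_k = float(mol.get("bend_k", 15.0))
    dih_k = float(mol.get("dihedral_k", 0.8))
    mult = int(mol.get("dihedral_mult", 1))
    n_sites = 6 * n_units
    terms = []
    for u in range(n_units):
        base = 6 * u
        for (i, j) in _CELL_BONDS:
            gi, gj = base + i, base + j
            if max(gi, gj) >= n_sites:
                continue  # terminal unit drops linkage-spanning terms
            terms.append(BondedTerm("bond", (gi, gj), (bond_k, _dist(ext[gi], ext[gj]))))
        for (i, j, k) in _CELL_BENDS:
            g = (base + i, base + j, base + k)
            if max(g) >= n_sites:
                continue
            terms.append(BondedTerm("bend", g, (bend_k, _angle(*[ext[x] for x in g]))))
        for (i, j, k, l) in _CELL_DIHEDRALS:
            g = (base + i, base + j, base + k, base + l)
            if max(g) >= n_sites:
                continue
            phi = _dihedral(*[ext[x] for x in g])
            terms.append(BondedTerm("dihedral", g, (dih_k, float(mult),
                                                    mult * phi - np.pi)))
    site_types = [_CELL_ORDER[i % 6] for i in range(n_sites)]
    coords = coords - coords.mean(axis=0)
    return _Unit(site_types, coords, [("cellulose", list(range(n_sites)))], terms, [])


# --- assembly -----------------------------------------------------------------


def _assemble(ff: ForceField, placed_units, box) -> Topology:
    """Concatenate placed units ((unit, coords (k,3)) tuples) into a Topology."""
    type_names = ff.type_names()
    index = {n: i for i, n in enumerate(type_names)}
    tids, coords, mol_ids, species = [], [], [], []
    terms, waters = [], []
    offset = 0
    mol_offset = 0
    for unit, xyz in placed_units:
        tids.extend(index[t] for t in unit.site_types)
        coords.append(xyz)
        for sp, _local in unit.molecules:
            species.append(sp)
        local_mol = np.empty(unit.n_sites, dtype=int)
        for mi, (sp, local) in enumerate(unit.molecules):
            local_mol[local] = mol_offset + mi
        mol_ids.append(local_mol)
        for t in unit.terms:
            terms.append(BondedTerm(t.kind, tuple(offset + s for s in t.sites), t.params))
        for (o, h1, h2) in unit.rigid_water_local:
            waters.append((offset + o, offset + h1, offset + h2))
        offset += unit.n_sites
        mol_offset += len(unit.molecules)
    return Topology(
        type_names=type_names,
        type_ids=np.array(tids, dtype=int),
        positions=np.vstack(coords) if coords else np.zeros((0, 3)),
        molecule_ids=np.concatenate(mol_ids) if mol_ids else np.zeros(0, int),
        molecule_species=species,
        bonded_terms=terms,
        rigid_waters=np.array(waters, dtype=int).reshape(-1, 3),
        box=np.asarray(box, dtype=float),
    )


def min_separation(positions: np.ndarray, box=None) -> float:
    """Smallest (periodic) site-site distance, via a k-d tree."""
    if len(positions) < 2:
        return np.inf
    if box is not None and np.all(np.asarray(box) > 0):
        box = np.asarray(box, float)
        pts = np.mod(positions, box)
        # guard against points landing exactly on the upper boundary
        pts = np.where(pts >= box, 0.0, pts)
        tree = cKDTree(pts, boxsize=box)
    else:
        tree = cKDTree(positions)
    d, _ = tree.query(tree.data, k=2)
    return float(np.min(d[:, 1]))


def _resolve_overlaps(placed, box, rng, min_sep: float = 0.8, max_iter: int = 200):
    """Re-rotate offending units about their centroid until no two sites from
    different units are closer than min_sep (periodic)."""
    box = np.asarray(box, float)
    n_units = len(placed)
    sizes = np.array([u.n_sites for u, _ in placed])
    owner = np.repeat(np.arange(n_units), sizes)
    for _ in range(max_iter):
        pos = np.vstack([xyz for _, xyz in placed])
        pts = np.mod(pos, box)
        pts = np.where(pts >= box, 0.0, pts)
        tree = cKDTree(pts, boxsize=box)
        pairs = tree.query_pairs(min_sep, output_type="ndarray")
        if len(pairs) == 0:
            return placed
        oa, ob = owner[pairs[:, 0]], owner[pairs[:, 1]]
        inter = oa != ob  # intra-unit distances are fixed by the template
        if not np.any(inter):
            return placed
        # rotate the higher-index unit of each clash, leaving unit 0 (e.g. a
        # solvated fiber) untouched
        bad_units = sorted(set(np.maximum(oa[inter], ob[inter]).tolist()))
        moved = False
        for ui in bad_units:
            unit, xyz = placed[ui]
            if unit.n_sites == 1:
                continue
            centroid = xyz.mean(axis=0)
            rot = _random_rotation(rng)
            placed[ui] = (unit, (xyz - centroid) @ rot.T + centroid)
            moved = True
        if not moved:
            break
    raise PackingError(
        f"could not resolve overlaps below {min_sep} Å after {max_iter} re-orientations"
    )


# --- public builders ----------------------------------------------------------


def build_lattice(units, box=None, target_density: float | None = None,
                  ff: ForceField | None = None, seed: int = 0,
                  min_sep: float = 0.8) -> Topology:
    """Place units (list of _Unit or (species, count) shorthand) on a simple
    cubic lattice of centroids with seeded random orientations.

    Either ``box`` (3 edges, Å) or ``target_density`` (g·cm⁻³) must be given;
    the density route sizes a cubic box from the total molar mass.
    """
    ff = ff or default_forcefield()
    expanded = []
    for entry in units:
        if isinstance(entry, _Unit):
            expanded.append(entry)
        else:
            species, count = entry
            proto = (_il_pair_unit(ff) if species == "il_pair"
                     else _simple_unit(ff, species))
            expanded.extend([proto] * int(count))
    if not expanded:
        raise ValueError("no units to place")
    if box is None:
        if target_density is None:
            raise ValueError("give either box or target_density")
        index = {n: i for i, n in enumerate(ff.type_names())}
        masses = np.array([ff.site_types[n].mass for n in ff.type_names()])
        total_mass = sum(float(np.sum(masses[[index[t] for t in u.site_types]]))
                         for u in expanded)
        volume = total_mass / (AVOG_CM3 * target_density)
        box = np.full(3, volume ** (1.0 / 3.0))
    box = np.asarray(box, dtype=float)

    n_units = len(expanded)
    n_side = int(np.ceil(n_units ** (1.0 / 3.0)))
    spacing = box / n_side
    rng = np.random.default_rng(seed)
    cells = np.array([(i, j, k) for i in range(n_side)
                      for j in range(n_side) for k in range(n_side)])
    order = rng.permutation(len(cells))[:n_units]
    placed = []
    for unit, cell in zip(expanded, cells[order]):
        center = (cell + 0.5) * spacing
        rot = _random_rotation(rng)
        placed.append((unit, unit.coords @ rot.T + center))
    placed = _resolve_overlaps(placed, box, rng, min_sep=min_sep)
    top = _assemble(ff, placed, box)
    sep = min_separation(top.positions, box)
    if sep < 0.5:
        raise PackingError(f"build produced overlapping sites (min separation {sep:.3f} Å)")
    return top


def build_bmimcl(n_pairs: int, box=None, target_density: float = 0.8,
                 ff: ForceField | None = None, seed: int = 0) -> Topology:
    """A [bmim][Cl] box: n_pairs ion pairs (5 sites each) on a seeded lattice.

    With no explicit box, the box is sized for ``target_density`` (default a
    loose 0.8 g·cm⁻³ pre-compression lattice; NPT brings it to the liquid).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    return build_lattice([("il_pair", n_pairs)], box=box,
                         target_density=None if box is not None else target_density,
                         ff=ff, seed=seed)


def build_cellulose_chain(n_units: int, ff: ForceField | None = None,
                          box=None) -> Topology:
    """A single linear cellulose chain of ``n_units`` cellobiose repeats."""
    ff = ff or default_forcefield()
    unit = _cellulose_chain_unit(ff, n_units)
    if box is None:
        length = 10.4 * n_units + 20.0
        box = np.array([length, 40.0, 40.0])
    box = np.asarray(box, float)
    xyz = unit.coords + box / 2.0
    return _assemble(ff, [(unit, xyz)], box)


def build_fiber(n_chains: int = 36, n_units: int = 10, spacing: float = 6.0,
                ff: ForceField | None = None, box=None) -> Topology:
    """Parallel cellulose chains on an Iα-like two-row staggered lattice.

    The native-cellulose crystal packing is reduced to what matters for a
    6-bead chain model: parallel chains at a configurable lattice spacing.
    """
    if n_chains < 1 or n_units < 1:
        raise ValueError("counts must be >= 1")
    ff = ff or default_forcefield()
    unit = _cellulose_chain_unit(ff, n_units)
    n_side = int(np.ceil(np.sqrt(n_chains)))
    length = 10.4 * n_units
    if box is None:
        width = max(n_side * spacing + 30.0, 40.0)
        box = np.array([length + 30.0, width, width])
    box = np.asarray(box, float)
    offsets = []
    for c in range(n_chains):
        iy, iz = divmod(c, n_side)
        offsets.append((0.0, iy * spacing, iz * spacing + (iy % 2) * spacing / 2.0))
    offsets = np.array(offsets)
    offsets -= offsets.mean(axis=0)
    placed = [(unit, unit.coords + off + box / 2.0) for off in offsets]
    top = _assemble(ff, placed, box)
    if min_separation(top.positions, box) < 0.5:
        raise PackingError("fiber chains overlap; increase spacing")
    return top


def chain_axis_positions(top: Topology) -> np.ndarray:
    """Per-chain centroid (y,z) coordinates, for fiber-lattice audits."""
    out = []
    for m in range(top.n_molecules):
        mask = top.molecule_ids == m
        if top.molecule_species[m] == "cellulose":
            out.append(top.positions[mask][:, 1:].mean(axis=0))
    return np.array(out)


def min_interchain_distance(top: Topology) -> float:
    """Minimum distance between cellulose chain axes (y–z centroids)."""
    axes = chain_axis_positions(top)
    if len(axes) < 2:
        return np.inf
    d = axes[:, None, :] - axes[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    iu = np.triu_indices(len(axes), k=1)
    return float(np.min(dist[iu]))


def solvate(fiber: Topology, comp: CompositionSpec, box=None,
            ff: ForceField | None = None, seed: int = 0,
            exclusion_shell: float = 3.0, jitter: float = 0.3,
            target_density: float = 0.95, min_sep: float = 0.7) -> Topology:
    """Center the fiber and place IL pairs and waters on a jittered grid
    outside an exclusion shell around the fiber."""
    ff = ff or default_forcefield()
    rng = np.random.default_rng(seed)
    fiber_pos = fiber.positions.copy()
    extent = fiber_pos.max(axis=0) - fiber_pos.min(axis=0)
    il_unit = _il_pair_unit(ff)
    water_unit = _simple_unit(ff, "water")

    if box is None:
        masses_by_name = {n: ff.site_types[n].mass for n in ff.type_names()}
        fiber_mass = float(sum(masses_by_name[n] for n in
                               np.array(fiber.type_names, dtype=object)[fiber.type_ids]))
        solvent_mass = comp.n_il_pairs * 174.675 + comp.n_water * 18.015
        volume = (fiber_mass + solvent_mass) / (AVOG_CM3 * target_density)
        x_edge = max(extent[0] + 12.0, volume ** (1.0 / 3.0))
        yz_edge = np.sqrt(volume / x_edge)
        box = np.array([x_edge, yz_edge, yz_edge])
    box = np.asarray(box, dtype=float)
    if np.any(extent + 4.0 > box):
        raise PackingError("fiber does not fit the requested box with margin")

    # center the fiber
    fiber_pos += box / 2.0 - (fiber_pos.max(axis=0) + fiber_pos.min(axis=0)) / 2.0

    n_solvent = comp.n_il_pairs + comp.n_water
    placed = []
    if n_solvent:
        # candidate grid dense enough to survive the exclusion-shell filter
        spacing = (np.prod(box) / max(n_solvent * 1.8, 1)) ** (1.0 / 3.0)
        counts = np.maximum((box / spacing).astype(int), 1)
        gx, gy, gz = (np.arange(c) * (box[d] / c) + box[d] / (2 * c)
                      for d, c in enumerate(counts))
        grid = np.array(np.meshgrid(gx, gy, gz, indexing="ij")).reshape(3, -1).T
        if len(fiber_pos):
            pts = np.where(np.mod(fiber_pos, box) >= box, 0.0, np.mod(fiber_pos, box))
            tree = cKDTree(pts, boxsize=box)
            d, _ = tree.query(grid)
            grid = grid[d > exclusion_shell]
        if len(grid) < n_solvent:
            raise PackingError(
                f"only {len(grid)} placement points for {n_solvent} solvent units; "
                f"box too small"
            )
        order = rng.permutation(len(grid))[:n_solvent]
        sites = grid[order]
        units = [il_unit] * comp.n_il_pairs + [water_unit] * comp.n_water
        for unit, center in zip(units, sites):
            rot = _random_rotation(rng)
            off = rng.uniform(-jitter, jitter, size=3)
            placed.append((unit, unit.coords @ rot.T + center + off))

    fiber_unit = _Unit(
        [fiber.type_names[t] for t in fiber.type_ids], fiber_pos,
        [(fiber.molecule_species[m], np.flatnonzero(fiber.molecule_ids == m).tolist())
         for m in range(fiber.n_molecules)],
        fiber.bonded_terms, [],
    )
    all_placed = [(fiber_unit, fiber_pos)] + placed
    if placed:
        all_placed = _resolve_overlaps(all_placed, box, rng, min_sep=min_sep)
    top = _assemble(ff, all_placed, box)
    sep = min_separation(top.positions, box)
    if sep < 0.5:
        raise PackingError(f"solvation left overlapping sites (min sep {sep:.3f} Å)")
    return top


def mass_fraction(top: Topology, species: str, ff: ForceField | None = None,
                  of=None) -> float:
    """Mass fraction of a species (or alias group 'il', 'water', 'cellulose').

    ``of`` restricts the denominator to a list of species/aliases (default:
    the whole system), e.g. ``of=('cellulose', 'il')`` for cellulose-in-IL.
    """
    ff = ff or default_forcefield()
    if species not in SPECIES_GROUPS and species not in set(top.molecule_species):
        raise KeyError(f"unknown species {species!r}")
    masses = top.masses(ff)
    mol_species = np.array(top.molecule_species, dtype=object)[top.molecule_ids]

    def group_mass(label):
        members = SPECIES_GROUPS.get(label, (label,))
        return float(masses[np.isin(mol_species, members)].sum())

    numer = group_mass(species)
    if of is None:
        denom = float(masses.sum())
    else:
        denom = sum(group_mass(l) for l in of)
    if denom == 0:
        raise ZeroDivisionError("denominator species have zero mass")
    return numer / denom
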