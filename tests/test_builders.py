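"""System builders: ionic-liquid boxes, cellulose chains, fibers, solvation."""

import numpy as np
import pytest

from miecg.builders import (
    CELLULOSE_UNIT_TEMPLATE_COUNTS,
    CompositionSpec,
    PackingError,
    build_bmimcl,
    build_cellulose_chain,
    build_fiber,
    build_lattice,
    cellulose_pair_combinations,
    mass_fraction,
    min_interchain_distance,
    min_separation,
    solvate,
)


class TestIonicLiquid:
    def test_site_count_five_per_pair(self, ff):
        top = build_bmimcl(16, ff=ff, seed=0)
        assert top.n_sites == 16 * 5
        assert top.n_molecules == 32  # cation + anion per pair

    def test_single_pair_neutral(self, ff):
        top = build_bmimcl(1, box=np.full(3, 40.0), ff=ff, seed=0)
        assert top.n_sites == 5
        assert top.net_charge(ff) == pytest.approx(0.0, abs=1e-12)

    def test_cation_bonded_template(self, ff):
        top = build_bmimcl(4, ff=ff, seed=1)
        counts = top.term_counts()
        # chain cation I3–I1–I2–CT: 3 bonds, 2 bends, 1 dihedral per cation
        assert counts == {"bond": 12, "bend": 8, "dihedral": 4}

    def test_charge_neutrality_any_build(self, ff):
        for n in (2, 7, 32):
            top = build_bmimcl(n, ff=ff, seed=n)
            assert abs(top.net_charge(ff)) < 1e-10


class TestCellulose:
    def test_six_sites_per_cellobiose(self, ff):
        top = build_cellulose_chain(10, ff=ff)
        assert top.n_sites == 60
        assert top.n_molecules == 1

    def test_per_unit_template_is_7_4_8(self):
        assert CELLULOSE_UNIT_TEMPLATE_COUNTS == {"bond": 7, "bend": 4, "dihedral": 8}

    @pytest.mark.parametrize("n_units", [1, 2, 5, 10])
    def test_chain_term_counts_follow_template(self, ff, n_units):
        # each unit owns the linkage-spanning terms to the next unit; the
        # terminal unit drops them (1 bond, 1 bend, 5 dihedrals)
        top = build_cellulose_chain(n_units, ff=ff)
        counts = top.term_counts()
        assert counts["bond"] == 7 * n_units - 1
        assert counts["bend"] == 4 * n_units - 1
        assert counts["dihedral"] == 8 * n_units - 5

    def test_21_unique_type_pair_combinations(self):
        # enumeration oracle: C(6,2) + 6 self pairs
        from itertools import combinations_with_replacement

        types = ("C11", "C14", "C16", "C21", "C24", "C26")
        assert len(list(combinations_with_replacement(types, 2))) == 21
        assert cellulose_pair_combinations() == 21

    def test_invalid_unit_count(self, ff):
        with pytest.raises(ValueError):
            build_cellulose_chain(0, ff=ff)


class TestFiber:
    def test_default_fiber_counts(self, ff):
        top = build_fiber(36, 10, ff=ff)
        assert top.n_sites == 2160
        assert top.n_molecules == 36
        assert all(s == "cellulose" for s in top.molecule_species)

    def test_single_chain_matches_chain_builder(self, ff):
        fiber = build_fiber(1, 5, ff=ff)
        chain = build_cellulose_chain(5, ff=ff)
        # same internal geometry up to a rigid translation
        d_f = fiber.positions - fiber.positions.mean(axis=0)
        d_c = chain.positions - chain.positions.mean(axis=0)
        assert np.allclose(d_f, d_c, atol=1e-9)

    def test_interchain_spacing_audit(self, ff):
        spacing = 6.0
        top = build_fiber(9, 4, spacing=spacing, ff=ff)
        assert min_interchain_distance(top) >= spacing - 1e-9


class TestLattice:
    def test_eight_molecules_on_2x2x2(self, ff):
        top = build_lattice([("water", 8)], box=np.full(3, 20.0), ff=ff, seed=0)
        # centroids occupy the 8 cells of a 2×2×2 grid
        cents = np.array([top.positions[top.molecule_ids == m].mean(axis=0)
                          for m in range(8)])
        cells = np.round((cents - 5.0) / 10.0).astype(int)
        assert len({tuple(c) for c in cells}) == 8

    def test_density_sized_box_edge(self, ff):
        # 256 pairs at 1.1 g/cm³: edge from mass/density arithmetic
        top = build_lattice([("il_pair", 4)], target_density=1.1, ff=ff, seed=0)
        expected_v = 4 * 174.675 / (0.602214076 * 1.1)
        assert np.prod(top.box) == pytest.approx(expected_v, rel=1e-6)
        edge_256 = (256 * 174.675 / (0.602214076 * 1.1)) ** (1 / 3)
        assert 40.0 < edge_256 < 41.0  # the full-size box sits at ~40.7 Å

    def test_determinism_bit_identical(self, ff):
        a = build_bmimcl(12, ff=ff, seed=77)
        b = build_bmimcl(12, ff=ff, seed=77)
        assert np.array_equal(a.positions, b.positions)
        c = build_bmimcl(12, ff=ff, seed=78)
        assert not np.array_equal(a.positions, c.positions)

    def test_min_separation_contract(self, ff):
        top = build_bmimcl(32, ff=ff, seed=5)
        assert min_separation(top.positions, top.box) >= 0.5

    def test_overcrowded_box_raises(self, ff):
        with pytest.raises(PackingError):
            build_lattice([("il_pair", 64)], box=np.full(3, 10.0), ff=ff, seed=0)


@pytest.fixture(scope="module")
def solvated(ff):
    fiber = build_fiber(2, 3, ff=ff)
    comp = CompositionSpec(n_il_pairs=40, n_water=54, n_chains=2,
                           n_cellobiose_per_chain=3)
    return solvate(fiber, comp, ff=ff, seed=3, target_density=0.9)


class TestSolvate:
    def test_site_count_arithmetic(self, solvated):
        assert solvated.n_sites == 2 * 3 * 6 + 5 * 40 + 3 * 54

    def test_fiber_centered(self, solvated):
        cell_pos = solvated.positions[
            np.isin(np.array(solvated.molecule_species, dtype=object)[
                solvated.molecule_ids], ["cellulose"])]
        center = (cell_pos.max(axis=0) + cell_pos.min(axis=0)) / 2
        assert np.allclose(center, solvated.box / 2, atol=1.0)

    def test_no_overlaps(self, solvated):
        assert min_separation(solvated.positions, solvated.box) >= 0.5

    def test_zero_water_zero_fraction(self, ff):
        fiber = build_fiber(1, 2, ff=ff)
        comp = CompositionSpec(n_il_pairs=10, n_water=0, n_chains=1,
                               n_cellobiose_per_chain=2)
        top = solvate(fiber, comp, ff=ff, seed=1, target_density=0.7)
        assert mass_fraction(top, "water", ff=ff) == 0.0

    def test_unplaceable_counts_raise(self, ff):
        fiber = build_fiber(1, 2, ff=ff)
        comp = CompositionSpec(n_il_pairs=500, n_water=500, n_chains=1,
                               n_cellobiose_per_chain=2)
        with pytest.raises(PackingError):
            solvate(fiber, comp, box=np.full(3, 30.0), ff=ff, seed=1)


class TestMassFraction:
    def test_pure_water_is_unity(self, ff):
        top = build_lattice([("water", 5)], box=np.full(3, 20.0), ff=ff, seed=0)
        assert mass_fraction(top, "water", ff=ff) == pytest.approx(1.0)

    def test_water_plus_chloride_arithmetic(self, ff):
        top = build_lattice([("water", 1), ("chloride", 1)],
                            box=np.full(3, 20.0), ff=ff, seed=0)
        expect = 18.015 / (18.015 + 35.453)
        assert mass_fraction(top, "water", ff=ff) == pytest.approx(expect, rel=1e-4)

    def test_unknown_species_rejected(self, ff):
        top = build_lattice([("water", 2)], box=np.full(3, 20.0), ff=ff, seed=0)
        with pytest.raises(KeyError):
            mass_fraction(top, "ethanol", ff=ff)
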