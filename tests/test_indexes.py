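"""Spatial structure indexes: worked examples, the frozen 12-tree fixture,
range invariants and distributional behaviour across point patterns."""

import math

import numpy as np
import pytest

import fixture_twelve_expected as frozen
from conftest import make_stand, make_tree
from oracles import derive_indexes
from standopt import (StructureConfig, canopy_density, competition_covariates,
                      complete_mingling, crown_competition_index,
                      dominant_height, generate_synthetic_stand,
                      neighborhood_comparison, objective_from_report,
                      stratification_index, structure_report,
                      uniform_angle_index, voronoi_units)
from standopt.geometry import SpatialUnit


def star_stand(neighbours, ref=None, radius=20.0):
    """Reference tree at the origin surrounded by explicit neighbours."""
    trees = [ref or make_tree(tid=1)]
    trees += [make_tree(tid=i + 2, **kw) for i, kw in enumerate(neighbours)]
    stand = make_stand(trees, radius=radius)
    unit = SpatialUnit(reference_id=1,
                       neighbour_ids=tuple(t.id for t in trees[1:]))
    return stand, unit


class TestUniformAngle:
    def test_perfect_cross_is_regular(self):
        stand, unit = star_stand([
            dict(x=0, y=5), dict(x=5, y=0), dict(x=0, y=-5), dict(x=-5, y=0)])
        assert uniform_angle_index(unit, stand) == 0.0

    def test_two_tight_pairs(self):
        # azimuths 0, 10, 180, 190 -> gaps 10, 170, 10, 170, two below 72
        neigh = [dict(x=5 * math.sin(math.radians(a)),
                      y=5 * math.cos(math.radians(a)))
                 for a in (0, 10, 180, 190)]
        stand, unit = star_stand(neigh)
        assert uniform_angle_index(unit, stand) == 0.5

    def test_standard_angle_is_72_for_four_neighbours(self):
        # gaps of 71 degrees count, 72 does not (strict inequality)
        neigh = [dict(x=5 * math.sin(math.radians(a)),
                      y=5 * math.cos(math.radians(a)))
                 for a in (0, 71, 143, 215)]
        stand, unit = star_stand(neigh)
        # gaps 71, 72, 72, 145->wrap 145: only the 71 gap is below 72
        assert uniform_angle_index(unit, stand) == pytest.approx(0.25)


class TestNeighborhoodComparison:
    def test_half_of_neighbours_larger(self):
        stand, unit = star_stand(
            [dict(x=3, y=0, dbh=25), dict(x=-3, y=0, dbh=15),
             dict(x=0, y=3, dbh=18), dict(x=0, y=-3, dbh=22)],
            ref=make_tree(tid=1, dbh=20))
        assert neighborhood_comparison(unit, stand) == 0.5

    def test_dominant_tree_scores_zero(self):
        stand, unit = star_stand(
            [dict(x=3, y=0, dbh=10), dict(x=-3, y=0, dbh=12)],
            ref=make_tree(tid=1, dbh=30))
        assert neighborhood_comparison(unit, stand) == 0.0

    def test_equal_dbh_tie_counts_zero(self):
        stand, unit = star_stand([dict(x=3, y=0, dbh=20)],
                                 ref=make_tree(tid=1, dbh=20))
        assert neighborhood_comparison(unit, stand) == 0.0


class TestCompleteMingling:
    def test_monoculture_unit_scores_zero(self):
        stand, unit = star_stand([dict(x=3, y=0), dict(x=-3, y=0)],
                                 ref=make_tree(tid=1, species="pinus"))
        assert complete_mingling(unit, stand) == 0.0

    def test_four_distinct_foreign_species(self):
        neigh = [dict(x=3, y=0, species="a"), dict(x=-3, y=0, species="b"),
                 dict(x=0, y=3, species="c"), dict(x=0, y=-3, species="d")]
        stand, unit = star_stand(neigh, ref=make_tree(tid=1, species="e"))
        assert complete_mingling(unit, stand) \
            == pytest.approx(0.5 * ((1 - 4 / 25) + 1.0))

    def test_mixed_counts_example(self):
        # neighbours (A, A, B, C) around reference D
        neigh = [dict(x=3, y=0, species="A"), dict(x=-3, y=0, species="A"),
                 dict(x=0, y=3, species="B"), dict(x=0, y=-3, species="C")]
        stand, unit = star_stand(neigh, ref=make_tree(tid=1, species="D"))
        assert complete_mingling(unit, stand) \
            == pytest.approx(0.5 * ((1 - 6 / 25) + 0.75))


class TestDominantHeight:
    def test_top_k_count_from_area(self):
        # radius 20 -> 0.1256637 ha -> k = 12
        trees = [make_tree(tid=i + 1, x=(i % 10) - 5, y=(i // 10) - 5,
                           height=10 + i * 0.1) for i in range(30)]
        stand = make_stand(trees, radius=20.0)
        top12 = sorted((t.height for t in trees), reverse=True)[:12]
        assert dominant_height(stand) == pytest.approx(np.mean(top12))

    def test_terrain_term_added(self):
        trees = [make_tree(tid=1, height=10, rel_elev=2.0),
                 make_tree(tid=2, x=1, height=12, rel_elev=0.0)]
        stand = make_stand(trees, radius=6.0)  # k = 1
        assert dominant_height(stand) == pytest.approx(12.0)

    def test_k_equal_stand_size_means_everything(self):
        trees = [make_tree(tid=i + 1, x=i * 0.5, height=8 + i,
                           rel_elev=0.5 * i) for i in range(4)]
        stand = make_stand(trees, radius=12.0)  # k = 4 = stand size
        assert dominant_height(stand) \
            == pytest.approx(np.mean([8.5 * 0 + 8 + i + 0.5 * i
                                      for i in range(4)]))


class TestStratification:
    def test_single_layer_unit(self):
        stand, unit = star_stand([dict(x=3, y=0, height=12),
                                  dict(x=-3, y=0, height=11)],
                                 ref=make_tree(tid=1, height=12))
        assert stratification_index(unit, stand, h_d=15.0) \
            == pytest.approx(1.0 / 3.0)

    def test_two_layers_half_same(self):
        neigh = [dict(x=3, y=0, height=14), dict(x=-3, y=0, height=13),
                 dict(x=0, y=3, height=3), dict(x=0, y=-3, height=3.5)]
        stand, unit = star_stand(neigh, ref=make_tree(tid=1, height=14))
        # H_d = 15: layers split at 5 and 10; two of four share the top layer
        assert stratification_index(unit, stand, h_d=15.0) \
            == pytest.approx((2 / 3) * 0.5)

    def test_opposite_layers_contribute_zero(self):
        stand, unit = star_stand([dict(x=3, y=0, height=3.0)],
                                 ref=make_tree(tid=1, height=14))
        # |FL| difference 2 -> term 1 - 2/2 = 0; z = 2
        assert stratification_index(unit, stand, h_d=15.0) == 0.0


class TestCrownCompetition:
    def test_no_overlap_with_zero_sentinel(self):
        cfg = StructureConfig(no_overlap_value=0.0)
        stand, unit = star_stand([dict(x=15, y=0)], radius=30.0)
        assert crown_competition_index(unit, stand, cfg) == 0.0

    def test_identical_coincident_neighbour_gives_unity(self):
        ref = make_tree(tid=1, cw=2.0, height=10, cl=4.0)
        stand, unit = star_stand([dict(x=0.0, y=0.0, cw=2.0, height=10,
                                       cl=4.0)], ref=ref)
        assert crown_competition_index(unit, stand) == pytest.approx(1.0)

    def test_distant_neighbour_sentinel_one_over_pi(self):
        ref = make_tree(tid=1, cw=2.0, height=10, cl=4.0)
        stand, unit = star_stand([dict(x=15.0, y=0.0, cw=2.0, height=10,
                                       cl=4.0)], ref=ref, radius=30.0)
        assert crown_competition_index(unit, stand) \
            == pytest.approx(1.0 / math.pi)


class TestCanopyDensity:
    def test_no_crowns_zero(self):
        stand = make_stand([make_tree(tid=1, cw=1e-9)], radius=10.0)
        assert canopy_density(stand) == 0.0

    def test_single_giant_crown_covers_plot(self):
        stand = make_stand([make_tree(tid=1, cw=40.0, cl=5.0, height=12.0)],
                           radius=10.0)
        assert canopy_density(stand) == 1.0

    def test_two_disjoint_crowns_additive(self):
        stand = make_stand([
            make_tree(tid=1, x=-5, cw=4.0),
            make_tree(tid=2, x=5, cw=6.0)], radius=10.0)
        expected = (math.pi * 4 + math.pi * 9) / (math.pi * 100)
        assert canopy_density(stand) == pytest.approx(expected, abs=0.01)


class TestCovariates:
    def test_hegyi_single_neighbour(self):
        trees = [make_tree(tid=1, dbh=20), make_tree(tid=2, x=5, dbh=20),
                 make_tree(tid=3, x=0, y=9, dbh=10),
                 make_tree(tid=4, x=-9, y=-4, dbh=10)]
        cov = competition_covariates(make_stand(trees, radius=12.0))
        # tree 2's contribution to tree 1: 20 / (20 * 5) = 0.2
        assert cov.table.loc[1, "HCI"] >= 0.2

    def test_largest_tree_has_zero_bal(self):
        stand = generate_synthetic_stand(radius_m=12, density_per_ha=1500,
                                         seed=9)
        cov = competition_covariates(stand)
        biggest = max(stand.living(), key=lambda t: t.dbh)
        assert cov.table.loc[biggest.id, "BAL"] == 0.0

    def test_reineke_sdi_closed_form(self):
        # NT=1500/ha and Dq=15 cm -> SDI = 1500 * 0.6^1.605
        cov_expected = 1500 * 0.6 ** 1.605
        assert cov_expected == pytest.approx(660.75, abs=0.05)


class TestTwelveTreeFixture:
    def test_indexes_match_frozen_hand_derivation(self, twelve_tree_stand):
        rep = structure_report(twelve_tree_stand)
        assert sorted(rep.indexes.table.index) == sorted(frozen.PER_TREE)
        for tid, expected in frozen.PER_TREE.items():
            row = rep.indexes.table.loc[tid]
            for key, value in expected.items():
                assert row[key] == pytest.approx(value, abs=1e-10), \
                    f"tree {tid} index {key}"
        for key, value in frozen.MEANS.items():
            assert rep.indexes.means[key] == pytest.approx(value, abs=1e-10)
        for key, value in frozen.STDS.items():
            assert rep.indexes.stds[key] == pytest.approx(value, abs=1e-10)

    def test_derivation_reproduces_frozen_values(self):
        from conftest import TWELVE_TREE_RADIUS, twelve_tree_dicts
        per, means, stds, l_val = derive_indexes(twelve_tree_dicts(),
                                                 TWELVE_TREE_RADIUS)
        assert sorted(per) == sorted(frozen.PER_TREE)
        for tid, expected in frozen.PER_TREE.items():
            assert per[tid] == pytest.approx(expected, abs=1e-12)
        assert l_val == pytest.approx(frozen.L_OBJECTIVE, abs=1e-12)


class TestDistributionalBehaviour:
    def test_index_ranges_on_random_stands(self):
        for seed in range(6):
            stand = generate_synthetic_stand(
                radius_m=13, density_per_ha=2000,
                clustering=float(np.random.default_rng(seed).uniform(-0.5, 0.9)),
                seed=seed)
            t = structure_report(stand).indexes.table
            assert ((t["W"] >= 0) & (t["W"] <= 1)).all()
            assert ((t["U"] >= 0) & (t["U"] <= 1)).all()
            assert ((t["Mc"] >= 0) & (t["Mc"] <= 1)).all()
            assert ((t["S"] >= 0) & (t["S"] <= 1)).all()
            assert (t["CI"] >= 0).all()

    def test_w_mean_separates_point_patterns(self):
        def mean_w(clustering, seeds=8):
            vals = []
            for seed in range(seeds):
                stand = generate_synthetic_stand(
                    radius_m=16, density_per_ha=2000, clustering=clustering,
                    seed=seed)
                vals.append(structure_report(stand).indexes.means["W"])
            return float(np.mean(vals))

        assert 0.45 <= mean_w(0.0) <= 0.54      # random: near 0.496
        assert mean_w(-1.0) < 0.30              # lattice: strongly regular
        assert mean_w(1.0) > 0.55               # strong clustering

    def test_mingling_rises_as_dominance_falls(self):
        shares = [1.0, 0.8, 0.6, 0.4, 1 / 7]
        means = []
        from standopt.growth_models import REPLANT_SPECIES
        for share in shares:
            rest = (1 - share) / 6
            mix = {s: (share if s == "pinus_yunnanensis" else rest)
                   for s in REPLANT_SPECIES}
            mix = {k: v for k, v in mix.items() if v > 0}
            vals = [structure_report(generate_synthetic_stand(
                radius_m=13, density_per_ha=2000, species_mix=mix,
                seed=seed)).indexes.means["Mc"] for seed in range(3)]
            means.append(float(np.mean(vals)))
        assert all(a < b for a, b in zip(means, means[1:]))
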