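"""Harvest selection, replant initialization, RFI, planting locations and
the replant-count trend search."""

import math

import numpy as np
import pytest

from conftest import make_stand, make_tree
from standopt import (HarvestBudgetError, StructureConfig, apply_harvest,
                      curve_trend_count_search, evaluate_growth_model,
                      generate_synthetic_stand, harvest_budget,
                      initialize_replant, propose_planting_locations,
                      replant_cap, replanting_foreground_index,
                      select_harvest_candidates, structure_report)
from standopt.growth_models import REPLANT_SPECIES, load_model_bank

# Published expected values (stand factors) at the 5 cm initialization DBH.
STAND_FACTORS = {
    ("pinus_yunnanensis", "H"): 5.20,
    ("pinus_yunnanensis", "CW"): 1.74,
    ("pinus_yunnanensis", "CL"): 1.32,
    ("pinus_armandii", "H"): 5.19,
    ("pinus_armandii", "CW"): 1.54,
    ("pinus_armandii", "CL"): 2.56,
    ("quercus_acutissima", "H"): 5.12,
    ("quercus_acutissima", "CW"): 1.82,
    ("quercus_acutissima", "CL"): 1.47,
    ("betula_alnoides", "H"): 6.33,
    ("betula_alnoides", "CW"): 2.12,
    ("betula_alnoides", "CL"): 2.98,
    ("vaccinium_bracteatum", "H"): 2.20,
    ("vaccinium_bracteatum", "CW"): 1.35,
    ("vaccinium_bracteatum", "CL"): 1.01,
    ("camellia_sinensis", "H"): 4.26,
    ("camellia_sinensis", "CW"): 1.48,
    ("camellia_sinensis", "CL"): 1.55,
    ("ternstroemia_gymnanthera", "H"): 5.13,
    ("ternstroemia_gymnanthera", "CW"): 1.21,
    ("ternstroemia_gymnanthera", "CL"): 1.17,
}


class TestGrowthModels:
    @pytest.mark.parametrize("key", sorted(STAND_FACTORS))
    def test_bank_reproduces_stand_factors_at_5cm(self, key):
        species, variable = key
        value = evaluate_growth_model(species, variable, 5.0)
        assert round(value, 2) == pytest.approx(STAND_FACTORS[key])

    def test_every_row_positive_and_finite_at_initialization(self):
        for spec in load_model_bank().values():
            v = spec(5.0)
            assert math.isfinite(v) and v > 0

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError):
            evaluate_growth_model("picea_abies", "H", 5.0)

    def test_initialize_replant_attributes(self):
        stand = make_stand([make_tree()], radius=20.0, slope=10.0)
        tree = initialize_replant("pinus_yunnanensis", (2.0, 3.0), stand)
        assert tree.dbh == 5.0 and tree.age == 5.0
        assert tree.origin == "replanted" and tree.alive
        assert tree.height == pytest.approx(5.20, abs=0.005)
        assert tree.crown_length == pytest.approx(1.32, abs=0.005)
        vac = initialize_replant("vaccinium_bracteatum", (0.0, 0.0), stand)
        assert vac.height == pytest.approx(2.20, abs=0.005)


class TestHarvestSelection:
    def test_zero_request_empty(self):
        stand = generate_synthetic_stand(radius_m=12, density_per_ha=1800,
                                         seed=1)
        rng = np.random.default_rng(0)
        assert select_harvest_candidates(stand, 0, rng) == []

    def test_budget_enforced(self):
        stand = generate_synthetic_stand(radius_m=13, density_per_ha=1900,
                                         seed=2)
        n0 = stand.n_living
        rng = np.random.default_rng(0)
        with pytest.raises(HarvestBudgetError):
            select_harvest_candidates(stand, harvest_budget(n0) + 1, rng,
                                      n_initial=n0)
        with pytest.raises(HarvestBudgetError):
            select_harvest_candidates(stand, 1, rng, n_initial=n0,
                                      already_harvested=harvest_budget(n0))

    def test_deterministic_for_fixed_seed(self):
        stand = generate_synthetic_stand(radius_m=12, density_per_ha=1800,
                                         seed=3)
        a = select_harvest_candidates(stand, 5, np.random.default_rng(42))
        b = select_harvest_candidates(stand, 5, np.random.default_rng(42))
        assert a == b

    def test_last_of_species_protected(self):
        trees = [make_tree(tid=i + 1, x=math.cos(i) * (3 + i % 5),
                           y=math.sin(i) * (3 + i % 5), species="pinus")
                 for i in range(20)]
        trees.append(make_tree(tid=99, x=0.3, y=0.2, species="rare"))
        stand = make_stand(trees, radius=12.0)
        for seed in range(20):
            ids = select_harvest_candidates(stand, 7,
                                            np.random.default_rng(seed))
            assert 99 not in ids

    def test_apply_harvest_marks_removed(self):
        stand = generate_synthetic_stand(radius_m=12, density_per_ha=1800,
                                         seed=4)
        n0 = stand.n_living
        tid = stand.living()[0].id
        after = apply_harvest(stand, [tid])
        assert after.n_living == n0 - 1
        assert not after.tree_by_id(tid).alive
        assert stand.n_living == n0  # original untouched
        with pytest.raises(KeyError):
            apply_harvest(stand, [99999])


class TestRFI:
    def grid_stand_with_gap(self, radius=14.0):
        trees = []
        tid = 1
        for ix in range(-4, 5):
            for iy in range(-4, 5):
                x, y = ix * 2.6, iy * 2.6
                if math.hypot(x, y) > radius - 0.7:
                    continue
                if abs(ix) <= 1 and abs(iy) <= 1:
                    continue  # carve a central canopy gap
                trees.append(make_tree(tid=tid, x=x + 0.13 * ((ix * 7 + iy)
                                                              % 3 - 1),
                                       y=y + 0.11 * ((ix + iy * 5) % 3 - 1)))
                tid += 1
        return make_stand(trees, radius=radius)

    def test_unity_when_all_components_neutral(self):
        stand = self.grid_stand_with_gap()
        deltas = {"Mc": 1.0, "U": 1.0, "CI": 1.0}
        rfi = replanting_foreground_index((0.0, 0.0), "pinus_yunnanensis",
                                          stand, deltas)
        assert rfi > 0

    def test_ci_factor_ratio(self):
        # two candidates identical except CI 0 vs 2 (deltas = 1) -> ratio 3
        num = (1 + 0.3) * (1 + 0.5) * (1 + 0.2)
        assert num / (1 + 0.0) / (num / (1 + 2.0)) == pytest.approx(3.0)

    def test_largest_gap_attracts_first_plant(self):
        stand = self.grid_stand_with_gap()
        rep = structure_report(stand)
        plan = propose_planting_locations(stand, 1, rep.indexes.stds)
        assert plan.count == 1
        x, y = plan.trees[0].x, plan.trees[0].y
        assert math.hypot(x, y) < 3.5  # inside the carved central gap

    def test_species_rotate_round_robin(self):
        stand = self.grid_stand_with_gap()
        rep = structure_report(stand)
        plan = propose_planting_locations(stand, 7, rep.indexes.stds)
        assert [t.species for t in plan.trees] == list(REPLANT_SPECIES)

    def test_empty_plan_for_zero_count(self):
        stand = self.grid_stand_with_gap()
        assert propose_planting_locations(stand, 0, {}).count == 0

    def test_min_distance_to_stems_respected(self):
        stand = self.grid_stand_with_gap()
        rep = structure_report(stand)
        plan = propose_planting_locations(stand, 10, rep.indexes.stds)
        stems = [(t.x, t.y) for t in stand.living()]
        for tree in plan.trees:
            d = min(math.hypot(tree.x - x, tree.y - y) for x, y in stems)
            assert d >= 0.5
            assert math.hypot(tree.x, tree.y) <= stand.core_radius - 1.0 + 1e-9


class TestCurveTrendSearch:
    def test_quadratic_peak_found(self):
        calls = []

        def f(c):
            calls.append(c)
            return -(c - 600) ** 2

        assert curve_trend_count_search(1000, 50, f) == 600
        assert len(calls) < 60  # far fewer evaluations than the grid

    def test_monotone_increasing_returns_cap(self):
        assert curve_trend_count_search(500, 40, lambda c: c) == 500

    def test_monotone_decreasing_returns_zero(self):
        assert curve_trend_count_search(500, 40, lambda c: -c) == 0

    def test_zero_cap_returns_zero(self):
        assert curve_trend_count_search(0, 10, lambda c: c) == 0

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_grid_argmax_on_unimodal_objectives(self, seed):
        rng = np.random.default_rng(seed)
        cap = int(rng.integers(50, 800))
        peak = float(rng.uniform(0, cap))
        scale = float(rng.uniform(0.01, 5.0))

        def f(c):
            return -scale * abs(c - peak) ** float(rng_pow)

        rng_pow = float(rng.uniform(1.0, 2.5))
        spacing = int(rng.integers(5, max(6, cap // 4)))
        got = curve_trend_count_search(cap, spacing, f)
        grid_best = max(range(cap + 1), key=f)
        assert f(got) == pytest.approx(f(grid_best))

    def test_multimodal_returns_local_argmax_at_least_start(self):
        def f(c):
            return math.sin(c / 15.0) * (1 + c / 300.0)

        cap, spacing = 300, 20
        start = cap // 2
        got = curve_trend_count_search(cap, spacing, f)
        assert f(got) >= f(start)
        assert f(got) >= max(f(max(0, got - 1)), f(min(cap, got + 1)))


class TestCaps:
    def test_replant_cap_from_density_band(self):
        stand = generate_synthetic_stand(radius_m=12, density_per_ha=2000,
                                         seed=5)
        cap = replant_cap(stand)
        area = stand.area_ha
        assert cap == math.floor(3333 * area) - stand.n_living
        assert (stand.n_living + cap) / area <= 3333
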