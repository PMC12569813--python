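"""Feature assembly, VIF screening, learners, PSO and the 5-year cycle."""

import numpy as np
import pandas as pd
import pytest

from standopt import (DEFAULT_LAW, FEATURE_SETS, advance_stand,
                      compute_features, fit_default_predictors,
                      generate_synthetic_stand, mortality_decision, pso_tune,
                      vif_filter)
from standopt.benchmarks import benchmark_bank


@pytest.fixture(scope="module")
def bank():
    return benchmark_bank(seed=1, n_stands=8)


@pytest.fixture(scope="module")
def law_stand():
    return generate_synthetic_stand(radius_m=12, density_per_ha=2000,
                                    clustering=0.4, seed=77,
                                    law=DEFAULT_LAW, noise_sd=0.0)


class TestFeatures:
    def test_derived_columns_consistent(self, law_stand):
        f = compute_features(law_stand)
        assert np.allclose(f["DBH_inv"], 1.0 / f["DBH"])
        assert np.allclose(f["DBH_sq"], f["DBH"] ** 2)
        assert np.allclose(f["HDR"], f["H"] / f["DBH"])
        assert not f.isna().any().any()

    def test_largest_tree_zero_bal(self, law_stand):
        f = compute_features(law_stand)
        assert f.loc[f["DBH"].idxmax(), "BAL"] == 0.0

    def test_task_feature_subsets(self):
        assert FEATURE_SETS["cw"] == ["AGE", "DBH_inv", "CL", "ASP", "SDI",
                                      "HDR", "NT"]
        assert FEATURE_SETS["mortality"] == ["DBH_inv", "H", "BAL", "HCI"]

    def test_dead_trees_excluded(self, law_stand):
        from dataclasses import replace
        victim = law_stand.living()[0].id
        stand = law_stand.with_trees([
            replace(t, alive=False) if t.id == victim else t
            for t in law_stand.trees])
        f = compute_features(stand)
        assert victim not in f.index


class TestVIF:
    def test_orthogonal_columns_kept(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame({"a": rng.normal(size=200),
                          "b": rng.normal(size=200)})
        assert vif_filter(m) == ["a", "b"]

    def test_duplicated_column_dropped(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=150)
        m = pd.DataFrame({"a": a, "b": a.copy(),
                          "c": rng.normal(size=150)})
        kept = vif_filter(m)
        assert len(kept) == 2 and "c" in kept

    def test_equicorrelated_design_matches_closed_form(self):
        # three columns with pairwise correlation r: R^2 of one on the other
        # two is 2r^2/(1+r), hence VIF = (1+r)/(1+r-2r^2)
        rng = np.random.default_rng(2)
        n = 200_000
        r = 0.9
        # construct exact equicorrelation via a shared factor
        lam = np.sqrt(r)
        shared = rng.normal(size=n)
        cols = {k: lam * shared + np.sqrt(1 - r) * rng.normal(size=n)
                for k in "abc"}
        m = pd.DataFrame(cols)
        from statsmodels.stats.outliers_influence import \
            variance_inflation_factor
        x = np.column_stack([m.to_numpy(), np.ones(n)])
        vif = variance_inflation_factor(x, 0)
        expected = (1 + r) / (1 + r - 2 * r * r)
        assert vif == pytest.approx(expected, rel=0.02)
        # threshold just below the closed form drops columns, above keeps all
        assert len(vif_filter(m, threshold=expected * 1.1)) == 3
        assert len(vif_filter(m, threshold=expected * 0.9)) < 3


class TestPSO:
    def test_sphere_optimum_found(self):
        best, val = pso_tune(lambda p: float(p @ p),
                             [(-5, 5), (-5, 5)], swarm=20, iterations=100,
                             seed=0)
        assert np.linalg.norm(best) < 1e-2

    def test_single_stationary_particle(self):
        best, val = pso_tune(lambda p: float(p[0] ** 2), [(2.0, 2.0)],
                             swarm=1, iterations=5, seed=0)
        assert best[0] == pytest.approx(2.0)

    def test_positions_stay_in_box(self):
        seen = []

        def obj(p):
            seen.append(p.copy())
            return float(p[0] ** 2)

        pso_tune(obj, [(-1, 1)], swarm=8, iterations=30, seed=3)
        arr = np.array(seen)
        assert arr.min() >= -1 - 1e-12 and arr.max() <= 1 + 1e-12

    def test_empty_bounds_rejected(self):
        with pytest.raises(ValueError):
            pso_tune(lambda p: 0.0, [])


class TestMortalityDecision:
    @pytest.mark.parametrize("prob, hci, dead", [
        (0.6, 0.8, True),
        (0.6, 0.5, False),   # competition gate fails
        (0.4, 0.9, False),   # probability gate fails
        (0.5, 0.9, False),   # strict inequality on the probability
    ])
    def test_joint_gate(self, prob, hci, dead):
        assert mortality_decision(prob, hci) is dead


class TestLearnerRecovery:
    def test_dbh_growth_r2_on_noiseless_law(self, bank):
        assert bank.metrics["dbh"] >= 0.95

    def test_mortality_threshold_rule_recovered(self, bank):
        assert bank.metrics["mortality"] >= 0.9

    def test_height_and_crown_models_fit(self, bank):
        assert bank.metrics["height"] >= 0.9
        assert bank.metrics["cw"] >= 0.9

    def test_same_seed_identical_predictions(self, law_stand):
        a = benchmark_bank(seed=3, n_stands=4)
        b = benchmark_bank(seed=3, n_stands=4)
        f = compute_features(law_stand)
        assert np.array_equal(a.predict("dbh", f), b.predict("dbh", f))

    def test_too_few_rows_rejected(self):
        tiny = generate_synthetic_stand(radius_m=12, density_per_ha=500,
                                        seed=0, law=DEFAULT_LAW)
        with pytest.raises(ValueError):
            fit_default_predictors([tiny.with_trees(tiny.trees[:20])],
                                   seed=0)


class TestAdvanceStand:
    def test_ages_advance_by_cycle_length(self, law_stand, bank):
        out = advance_stand(law_stand, bank)
        for before, after in zip(law_stand.trees, out.trees):
            if after.alive:
                assert after.age == before.age + 5.0

    def test_dbh_never_decreases(self, law_stand, bank):
        out = advance_stand(law_stand, bank)
        for before, after in zip(law_stand.trees, out.trees):
            assert after.dbh >= before.dbh - 1e-12

    def test_dead_trees_frozen_and_excluded(self, law_stand, bank):
        out = advance_stand(law_stand, bank)
        dead = [t for t in out.trees if not t.alive]
        if dead:  # crowns of dead trees are not updated
            for t in dead:
                orig = law_stand.tree_by_id(t.id)
                assert t.crown_width == orig.crown_width
        out2 = advance_stand(out, bank)
        assert {t.id for t in out2.trees if not t.alive} \
            >= {t.id for t in dead}

    def test_tree_count_non_increasing(self, law_stand, bank):
        out = advance_stand(law_stand, bank)
        assert out.n_living <= law_stand.n_living

    def test_five_cycle_mean_dbh_tracks_analytic_law(self, bank):
        """Learner-driven projection vs direct iteration of the true law."""
        stand = generate_synthetic_stand(radius_m=12, density_per_ha=1900,
                                         clustering=0.3, seed=55,
                                         law=DEFAULT_LAW, noise_sd=0.0)
        projected = stand
        for _ in range(5):
            projected = advance_stand(projected, bank)

        # oracle: apply the analytic law directly (same mortality rule)
        law = DEFAULT_LAW
        oracle = stand
        for _ in range(5):
            f = compute_features(oracle)
            dgi = pd.Series(law.dgi(f["DBH"], f["AGE"], f["BAL"]),
                            index=f.index)
            dead = pd.Series(law.dead(f["HCI"], f["DBH"]), index=f.index)
            from dataclasses import replace
            trees = {t.id: t for t in oracle.trees}
            for tid in f.index:
                t = trees[tid]
                trees[tid] = replace(
                    t, age=t.age + 5.0, dbh=t.dbh + float(dgi[tid]),
                    alive=not bool(dead[tid]))
            oracle = oracle.with_trees(trees.values())

        mean_proj = np.mean([t.dbh for t in projected.living()])
        mean_oracle = np.mean([t.dbh for t in oracle.living()])
        assert mean_proj == pytest.approx(mean_oracle, rel=0.05)
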