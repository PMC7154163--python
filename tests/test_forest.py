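"""Forest construction modes, OOB machinery, determinism and mortality."""

import json

import numpy as np
import pandas as pd
import pytest

import cureforest as cf

from conftest import two_group_cohort


@pytest.fixture(scope="module")
def small_cohort():
    rng = np.random.default_rng(99)
    cohort = cf.generate_cure_cohort(
        120,
        cf.SignalSpec(covariates=[cf.CovariateEffect("w", "binary", alpha=1.0, beta=0.5)]),
        seed=rng)
    noise, kinds, _ = cf.generate_noise_snps(120, 9, seed=rng)
    return cohort.add_variables(noise, kinds)


class TestConfig:
    def test_defaults_match_study_settings(self):
        cfg = cf.ForestConfig()
        assert cfg.n_trees == 500 and cfg.min_node_size == 15

    def test_validation(self):
        with pytest.raises(ValueError):
            cf.ForestConfig(n_trees=0)
        with pytest.raises(ValueError):
            cf.ForestConfig(subsample_fraction=0.0)
        with pytest.raises(ValueError):
            cf.ForestConfig(mode="boosting")

    def test_subspace_size_ceiling_rule(self, small_cohort):
        cfg = cf.ForestConfig(n_trees=4, subsample_fraction=0.25, min_node_size=10, seed=1)
        forest = cf.fit_forest(small_cohort, cfg)
        for tree in forest.trees:
            assert tree.feature_subspace.size == int(np.ceil(0.25 * 10))  # m=10 -> 3


class TestFitForest:
    def test_all_censored_rejected(self):
        cohort = cf.Cohort(time=np.ones(40), event=np.zeros(40, dtype=int),
                           data=pd.DataFrame({"x": np.zeros(40)}),
                           kinds={"x": "binary"})
        with pytest.raises(ValueError, match="no events"):
            cf.fit_forest(cohort, cf.ForestConfig(n_trees=2, min_node_size=5))

    def test_seed_determinism(self, small_cohort):
        cfg = cf.ForestConfig(n_trees=6, subsample_fraction=0.5, min_node_size=10, seed=3)
        f1 = cf.fit_forest(small_cohort, cfg)
        f2 = cf.fit_forest(small_cohort, cfg)
        assert json.dumps(f1.to_dict()) == json.dumps(f2.to_dict())

    def test_bagging_equals_fraction_one(self, small_cohort):
        cfg_b = cf.ForestConfig(n_trees=4, mode="bagging", min_node_size=10, seed=5)
        cfg_s = cf.ForestConfig(n_trees=4, mode="subspace", subsample_fraction=1.0,
                                min_node_size=10, seed=5)
        fb = cf.fit_forest(small_cohort, cfg_b)
        fs = cf.fit_forest(small_cohort, cfg_s)
        X, _, _ = small_cohort.as_arrays()
        assert np.array_equal(cf.predict_ensemble_chf(fb, X).chf,
                              cf.predict_ensemble_chf(fs, X).chf)
        for tb, ts in zip(fb.trees, fs.trees):
            assert np.array_equal(tb.feature_subspace, ts.feature_subspace)

    def test_classical_mode_respects_subspace_membership(self, small_cohort):
        cfg = cf.ForestConfig(n_trees=4, mode="classical", min_node_size=10, seed=7)
        forest = cf.fit_forest(small_cohort, cfg)
        m = small_cohort.n_variables
        for tree in forest.trees:
            assert tree.split_variables() <= set(range(m))

    def test_serialization_round_trip(self, small_cohort, tmp_path):
        cfg = cf.ForestConfig(n_trees=3, subsample_fraction=0.5, min_node_size=10, seed=11)
        forest = cf.fit_forest(small_cohort, cfg)
        path = tmp_path / "forest.json"
        forest.save(path)
        clone = cf.SurvivalForest.load(path)
        X, _, _ = small_cohort.as_arrays()
        assert np.array_equal(cf.predict_ensemble_chf(clone, X).chf,
                              cf.predict_ensemble_chf(forest, X).chf)


class TestEnsemblePrediction:
    def test_single_tree_forest_equals_tree(self, small_cohort):
        forest = cf.fit_forest(small_cohort, cf.ForestConfig(
            n_trees=1, subsample_fraction=0.5, min_node_size=10, seed=2))
        X, _, _ = small_cohort.as_arrays()
        assert np.array_equal(cf.predict_ensemble_chf(forest, X).chf,
                              forest.trees[0].predict(X))

    def test_mean_equals_brute_force(self, small_cohort, rng):
        forest = cf.fit_forest(small_cohort, cf.ForestConfig(
            n_trees=7, subsample_fraction=0.5, min_node_size=10, seed=13))
        X, _, _ = small_cohort.as_arrays()
        rows = X[rng.choice(X.shape[0], 10, replace=False)]
        brute = np.mean([t.predict(rows) for t in forest.trees], axis=0)
        assert np.abs(cf.predict_ensemble_chf(forest, rows).chf - brute).max() < 1e-12

    def test_ensemble_chf_nondecreasing(self, small_cohort):
        forest = cf.fit_forest(small_cohort, cf.ForestConfig(
            n_trees=5, subsample_fraction=0.5, min_node_size=10, seed=17))
        X, _, _ = small_cohort.as_arrays()
        chf = cf.predict_ensemble_chf(forest, X).chf
        assert np.all(np.diff(chf, axis=1) >= -1e-12)


class TestOOB:
    def test_single_tree_inbag_subjects_missing(self, small_cohort):
        forest = cf.fit_forest(small_cohort, cf.ForestConfig(
            n_trees=1, subsample_fraction=0.5, min_node_size=10, seed=4))
        pred = cf.oob_predict(forest, small_cohort)
        inbag = forest.inbag_counts()[0]
        assert np.array_equal(pred.available, inbag == 0)
        assert np.all(np.isnan(pred.chf[inbag > 0]))

    def test_oob_never_uses_containing_tree(self, small_cohort):
        forest = cf.fit_forest(small_cohort, cf.ForestConfig(
            n_trees=20, subsample_fraction=0.5, min_node_size=10, seed=6))
        inbag = forest.inbag_counts()
        pred = cf.oob_predict(forest, small_cohort)
        # brute-force recomputation per subject from its OOB trees only
        X, _, _ = small_cohort.as_arrays()
        for i in range(0, small_cohort.n, 13):
            oob_trees = [t for b, t in enumerate(forest.trees) if inbag[b, i] == 0]
            assert pred.n_trees_used[i] == len(oob_trees)
            if oob_trees:
                brute = np.mean([t.predict(X[i:i + 1])[0] for t in oob_trees], axis=0)
                assert pred.chf[i] == pytest.approx(brute, abs=1e-12)

    def test_oob_fraction_near_closed_form(self):
        # expected OOB share (1 - 1/n)^n ~ 36.8% at n = 457
        n = 457
        rng = np.random.default_rng(42)
        w = rng.integers(0, 2, n).astype(float)
        t = np.where(w == 1, rng.exponential(0.5, n), rng.exponential(2.0, n))
        e = (t < 3.0).astype(int)
        cohort = cf.Cohort(time=t.clip(max=3.0), event=e,
                           data=pd.DataFrame({"w": w}), kinds={"w": "binary"})
        forest = cf.fit_forest(cohort, cf.ForestConfig(n_trees=300, seed=9))
        oob_frac = (forest.inbag_counts() == 0).mean()
        assert oob_frac == pytest.approx((1 - 1 / n) ** n, abs=0.01)

    def test_cohort_mismatch_rejected(self, small_cohort):
        forest = cf.fit_forest(small_cohort, cf.ForestConfig(
            n_trees=2, subsample_fraction=0.5, min_node_size=10, seed=8))
        other = two_group_cohort(30)
        with pytest.raises(ValueError, match="match"):
            cf.oob_predict(forest, other)


class TestMortality:
    def test_flat_zero(self):
        assert cf.mortality(np.zeros(10)) == 0.0

    def test_constant_one_on_ten_grid(self):
        assert cf.mortality(np.ones(10)) == 10.0

    def test_dominance_preserved(self, rng):
        f = np.cumsum(rng.random(20))
        g = f * 0.5
        assert cf.mortality(f) >= cf.mortality(g)

    def test_decreasing_input_rejected(self):
        with pytest.raises(ValueError):
            cf.mortality(np.array([1.0, 0.5]))
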