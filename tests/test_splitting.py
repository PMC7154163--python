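"""Nelson-Aalen plug-ins, the 2-df score statistic and the split search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines.statistics import logrank_test

import cureforest as cf
from cureforest.splitting import (SplitCandidate, best_split, enumerate_candidates,
                                  logrank_statistic, nelson_aalen, null_estimates,
                                  score_split_statistic)

from conftest import random_survival_data


class TestNelsonAalen:
    def test_single_event(self):
        na = nelson_aalen([1.0], [1])
        assert na(0.5) == 0.0 and na(1.0) == 1.0 and na(2.0) == 1.0

    def test_hand_computed_increments(self, toy_outcomes):
        na = nelson_aalen(*toy_outcomes)
        assert na(1.0) == pytest.approx(1 / 3)
        assert na(3.0) == pytest.approx(1 / 3 + 1.0)

    def test_all_censored_is_zero(self):
        na = nelson_aalen([1.0, 2.0], [0, 0])
        assert na(10.0) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nelson_aalen([], [])

    def test_nondecreasing_right_continuous(self, rng):
        t, e = random_survival_data(rng, 100, tie_round=1)
        na = nelson_aalen(t, e)
        grid = np.linspace(0, t.max() + 1, 200)
        assert np.all(np.diff(na(grid)) >= 0)


class TestNullEstimates:
    def test_hand_computed_plug_ins(self, toy_outcomes):
        ne = null_estimates(*toy_outcomes)
        assert ne.theta0_hat == pytest.approx(4 / 3)
        assert ne.h0_hat(1.0) == pytest.approx(-np.log(0.75), abs=1e-9)

    def test_terminal_clamp_keeps_h0_finite(self, toy_outcomes):
        ne = null_estimates(*toy_outcomes, epsilon=1e-6)
        # at the largest event time the ratio is exactly 1 and must be clamped
        assert np.isfinite(ne.h0_hat(3.0))
        assert ne.h0_hat(3.0) == pytest.approx(-np.log(1e-6), rel=1e-6)

    def test_single_event_case(self):
        ne = null_estimates([2.0, 3.0], [1, 0])
        assert ne.theta0_hat == pytest.approx(0.5)
        assert ne.event_times.tolist() == [2.0]

    def test_no_events_signals_unsplittable(self):
        with pytest.raises(ValueError, match="no events"):
            null_estimates([1.0, 2.0], [0, 0])


class TestScoreStatistic:
    def test_mirror_data_is_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 0, 1, 1, 0, 1])
        w = np.array([1, 1, 1, 0, 0, 0])
        res = score_split_statistic(t, e, w, null_estimates(t, e))
        assert res.u == pytest.approx([0.0, 0.0], abs=1e-12)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_subject_hand_computation(self):
        t, e, w = np.array([1.0, 2.0]), np.array([1, 1]), np.array([1, 0])
        res = score_split_statistic(t, e, w, null_estimates(t, e))
        assert res.u[0] == pytest.approx(0.5)
        assert res.u[1] == pytest.approx((1 + np.log(2 / 3)) * 0.5, abs=1e-9)
        assert res.statistic == pytest.approx(1.0, abs=1e-9)
        assert res.df_used == 1  # the two weight rows are proportional here

    def test_matches_loglik_gradient(self, rng):
        """(U_alpha, U_beta) is the exact score of the discrete counting-process
        likelihood whose group-1 hazard increments are the baseline Nelson-Aalen
        increments scaled by the model hazard ratio; check by central differences."""
        def loglik(t, e, w, ne, a, b):
            t_ev = ne.event_times
            base_inc = np.diff(np.r_[0.0, ne.na_cumhaz.y])
            ratio = np.exp(a + b) * np.exp(-ne.h0_hat.y * (np.exp(b) - 1.0))
            ll = 0.0
            for i in range(t.size):
                at_risk = t_ev <= t[i]
                inc = base_inc * ratio ** w[i]
                ll -= inc[at_risk].sum()
                if e[i] == 1:
                    ll += np.log(inc[np.searchsorted(t_ev, t[i])])
            return ll

        h = 1e-5
        worst = 0.0
        for _ in range(20):
            n = int(rng.integers(15, 31))
            t, e = random_survival_data(rng, n, censor_frac=0.3, tie_round=2)
            w = rng.integers(0, 2, n)
            if w.sum() in (0, n):
                w[0] = 1 - w[0]
            ne = null_estimates(t, e)
            res = score_split_statistic(t, e, w, ne)
            grad = np.array([
                (loglik(t, e, w, ne, h, 0) - loglik(t, e, w, ne, -h, 0)) / (2 * h),
                (loglik(t, e, w, ne, 0, h) - loglik(t, e, w, ne, 0, -h)) / (2 * h),
            ])
            denom = np.maximum(np.abs(res.u), 1e-8)
            worst = max(worst, float(np.max(np.abs(grad - res.u) / denom)))
        assert worst < 1e-3

    def test_alpha_component_is_logrank_numerator(self, rng):
        """U_alpha equals the textbook observed-minus-expected logrank numerator."""
        t, e = random_survival_data(rng, 20, tie_round=1)
        w = rng.integers(0, 2, 20)
        w[0], w[1] = 0, 1
        res = score_split_statistic(t, e, w, null_estimates(t, e))
        numerator = 0.0
        for tj in np.unique(t[e == 1]):
            at_risk = t >= tj
            d1 = int(np.sum((t == tj) & (e == 1) & (w == 1)))
            d = int(np.sum((t == tj) & (e == 1)))
            numerator += d1 - at_risk[w == 1].sum() * d / at_risk.sum()
        assert res.u[0] == pytest.approx(numerator, abs=1e-8)

    def test_label_symmetry(self, rng):
        t, e = random_survival_data(rng, 40, tie_round=1)
        w = rng.integers(0, 2, 40)
        w[:2] = [0, 1]
        ne = null_estimates(t, e)
        a = score_split_statistic(t, e, w, ne)
        b = score_split_statistic(t, e, 1 - w, ne)
        assert a.u == pytest.approx(-b.u, abs=1e-10)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-10)

    def test_permutation_variance_agrees_roughly(self, rng):
        t, e = random_survival_data(rng, 60)
        w = rng.integers(0, 2, 60)
        w[:2] = [0, 1]
        ne = null_estimates(t, e)
        hyp = score_split_statistic(t, e, w, ne)
        perm = score_split_statistic(t, e, w, ne, variance="permutation",
                                     n_permutations=2000, rng=1)
        # U is identical; the covariances agree up to permutation noise (the
        # statistic itself is ill-conditioned when V is nearly singular, so it
        # is not the quantity to compare)
        assert perm.u == pytest.approx(hyp.u, abs=1e-10)
        assert np.diag(perm.v) == pytest.approx(np.diag(hyp.v), rel=0.35)
        assert perm.statistic >= 0 and np.isfinite(perm.statistic)

    def test_one_sided_membership_rejected(self):
        ne = null_estimates([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            score_split_statistic([1.0, 2.0], [1, 1], [1, 1], ne)


class TestLogrank:
    def test_mirror_data_is_zero(self):
        t = np.array([1.0, 2.0, 1.0, 2.0])
        e = np.array([1, 1, 1, 1])
        assert logrank_statistic(t, e, [1, 1, 0, 0]) == pytest.approx(0.0)

    def test_two_subject_example(self):
        assert logrank_statistic([1.0, 2.0], [1, 1], [1, 0]) == pytest.approx(1.0)

    def test_matches_lifelines(self, rng):
        t, e = random_survival_data(rng, 50, tie_round=1)
        w = rng.integers(0, 2, 50)
        w[:2] = [0, 1]
        ours = logrank_statistic(t, e, w)
        ref = logrank_test(t[w == 1], t[w == 0], e[w == 1], e[w == 0])
        assert ours == pytest.approx(ref.test_statistic, abs=1e-8)


class TestEnumerateCandidates:
    def test_binary_gives_one_candidate(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        cands = enumerate_candidates(X, ["binary"])
        assert len(cands) == 1 and cands[0].rule == "gt"

    def test_genotype_gives_dominant_and_recessive(self):
        X = np.array([[0.0], [1.0], [2.0], [1.0]])
        cands = enumerate_candidates(X, ["genotype012"])
        assert [c.threshold for c in cands] == [0.5, 1.5]

    def test_continuous_midpoints(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        cands = enumerate_candidates(X, ["continuous"])
        assert [c.threshold for c in cands] == [1.5, 2.5, 3.5]

    def test_categorical_one_vs_rest(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        cands = enumerate_candidates(X, ["categorical"])
        assert len(cands) == 4 and all(c.rule == "eq" for c in cands)

    def test_candidate_count_accounting(self, rng):
        # b binary + g genotype + c categorical (L levels): b + 2g + cL at the root
        n, b, g, c, L = 60, 3, 4, 2, 4
        cols = [rng.integers(0, 2, n) for _ in range(b)]
        cols += [rng.integers(0, 3, n) for _ in range(g)]
        cols += [rng.integers(0, L, n) for _ in range(c)]
        X = np.column_stack(cols).astype(float)
        kinds = ["binary"] * b + ["genotype012"] * g + ["categorical"] * c
        cands = enumerate_candidates(X, kinds, min_node_size=1)
        assert len(cands) == b + 2 * g + c * L

    def test_min_size_filtering_on_unique_cases(self):
        # 9 vs 1 split is inadmissible at min_node_size=2
        X = np.r_[np.zeros(9), [1.0]][:, None]
        assert enumerate_candidates(X, ["binary"], min_node_size=2) == []
        assert len(enumerate_candidates(X, ["binary"], min_node_size=1)) == 1

    def test_quartile_mode_restricts_thresholds(self, rng):
        X = rng.normal(size=(100, 1))
        full = enumerate_candidates(X, ["continuous"])
        quart = enumerate_candidates(X, ["continuous"], quartile_mode=True)
        assert len(quart) == 3 < len(full)


class TestBestSplit:
    def test_perfect_separator_wins(self, rng):
        n = 60
        w = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        t = np.where(w == 1, rng.exponential(0.2, n), 5.0)
        e = np.where(w == 1, 1, 0)
        noise = rng.integers(0, 3, (n, 5)).astype(float)
        X = np.column_stack([noise[:, :2], w, noise[:, 2:]])
        kinds = ["genotype012"] * 2 + ["binary"] + ["genotype012"] * 3
        cand, stat = best_split(t, e, X, kinds, criterion="score", min_node_size=5)
        assert cand.var == 2 and stat > 0

    def test_tie_break_lowest_variable_id(self, rng):
        t, e = random_survival_data(rng, 30)
        col = rng.integers(0, 2, 30).astype(float)
        col[:2] = [0, 1]
        X = np.column_stack([col, col])  # identical columns, identical statistics
        cand, _ = best_split(t, e, X, ["binary", "binary"], criterion="logrank")
        assert cand.var == 0

    def test_no_events_returns_none(self):
        X = np.array([[0.0], [1.0]])
        assert best_split([1.0, 2.0], [0, 0], X, ["binary"]) is None

    def test_no_admissible_candidates_returns_none(self):
        X = np.zeros((10, 1))  # constant column: nothing to split on
        t = np.linspace(1, 2, 10)
        assert best_split(t, np.ones(10, dtype=int), X, ["binary"]) is None

    def test_score_equals_single_statistic_on_winner(self, rng):
        t, e = random_survival_data(rng, 50, tie_round=1)
        X = rng.integers(0, 3, (50, 8)).astype(float)
        found = best_split(t, e, X, ["genotype012"] * 8, criterion="score")
        cand, stat = found
        res = score_split_statistic(t, e, cand.membership(X[:, cand.var]),
                                    null_estimates(t, e))
        assert stat == pytest.approx(res.statistic, rel=1e-10)
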