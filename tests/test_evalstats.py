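"""R^2 scoring, whiteness testing, CV plans and model comparison."""
import numpy as np
import pytest
from scipy import stats

from neurosysid import errors
from neurosysid.datatypes import Recording
from neurosysid.evalstats import (build_cv_plan, chi2_whiteness_univariate,
                                  evaluate_model, portmanteau_q,
                                  r2_per_channel, signed_rank_compare,
                                  whiteness_test)
from neurosysid.synthgen import gen_stable_var


class TestR2:
    def test_perfect_prediction(self):
        y = np.random.default_rng(0).standard_normal((3, 20))
        assert np.all(r2_per_channel(y, y).r2 == 1.0)

    def test_test_mean_prediction_scores_zero(self):
        y = np.random.default_rng(1).standard_normal((2, 50))
        pred = np.repeat(y.mean(axis=1, keepdims=True), 50, axis=1)
        np.testing.assert_allclose(r2_per_channel(y, pred).r2, 0.0,
                                   atol=1e-12)

    def test_hand_worked_negative_value(self):
        # actual [1,2,3], predicted [3,3,3]: SST=2, SSE=5 -> R^2 = -1.5
        out = r2_per_channel(np.array([[1.0, 2.0, 3.0]]),
                             np.array([[3.0, 3.0, 3.0]]))
        assert out.r2[0] == pytest.approx(-1.5)

    def test_constant_channel_gets_nan_sentinel(self):
        actual = np.vstack([np.ones(10), np.arange(10.0)])
        out = r2_per_channel(actual, actual * 0.9)
        assert np.isnan(out.r2[0]) and np.isfinite(out.r2[1])
        assert out.median == out.r2[1]

    def test_zero_model_r2_vanishes_on_white_noise(self):
        e = np.random.default_rng(2).standard_normal((1, 10_000))
        pred = e[:, :-1]
        out = r2_per_channel(e[:, 1:], pred)
        assert abs(out.r2[0] + 1.0) < 0.06  # zero model on white noise: -1
        # and the mean predictor itself scores ~0 by construction
        const = np.full_like(e[:, 1:], e[0, 1:].mean())
        assert abs(r2_per_channel(e[:, 1:], const).r2[0]) < 1e-12


def _brute_force_q(e, M):
    n, N = e.shape
    R = [sum(np.outer(e[:, t + i], e[:, t]) for t in range(N - M)) / (N - M)
         for i in range(M + 1)]
    R0inv = np.linalg.pinv(R[0], rcond=1e-10)
    return (N - M) * sum(np.trace(R[i].T @ R0inv @ R[i] @ R0inv)
                         for i in range(1, M + 1))


class TestPortmanteau:
    def test_zero_residuals_give_zero_statistic(self):
        assert portmanteau_q(np.zeros((2, 30)), 5) == 0.0

    def test_matches_independent_brute_force_evaluation(self):
        e = np.random.default_rng(3).standard_normal((2, 6))
        assert portmanteau_q(e, 2) == pytest.approx(_brute_force_q(e, 2))

    def test_detects_strong_autocorrelation(self):
        # AR(1) residuals with coefficient 0.9 must be rejected
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            e = np.empty((2, 1000))
            e[:, 0] = rng.standard_normal(2)
            innov = rng.standard_normal((2, 1000))
            for t in range(1, 1000):
                e[:, t] = 0.9 * e[:, t - 1] + innov[:, t]
            wt = whiteness_test(e, M=20, seed=10_000 + seed)
            hits += wt.ratio > 1.0
        assert hits >= 95

    def test_invariant_to_channel_permutation_and_recombination(self):
        e = np.random.default_rng(4).standard_normal((3, 400))
        q0 = portmanteau_q(e, 10)
        assert portmanteau_q(e[[2, 0, 1]], 10) == pytest.approx(q0, abs=1e-8)
        T = np.array([[2.0, 1.0, 0.0], [0.0, 1.0, 3.0], [1.0, 0.0, 1.0]])
        assert portmanteau_q(T @ e, 10) == pytest.approx(q0, abs=1e-8)

    def test_invalid_lag_count(self):
        with pytest.raises(errors.InvalidParameterError):
            portmanteau_q(np.zeros((1, 10)), 10)


class TestWhitenessRandomization:
    def test_threshold_uses_exactly_n_shuffles(self):
        e = np.random.default_rng(5).standard_normal((2, 200))
        wt = whiteness_test(e, M=10, n_shuffles=100, seed=1)
        assert wt.n_shuffles == 100 and wt.Q_thr > 0

    def test_deterministic_given_seed(self):
        e = np.random.default_rng(6).standard_normal((2, 150))
        a = whiteness_test(e, M=10, seed=9)
        b = whiteness_test(e, M=10, seed=9)
        assert a.Q_thr == b.Q_thr and a.Q == b.Q

    def test_few_shuffles_warn(self):
        e = np.random.default_rng(7).standard_normal((1, 100))
        with pytest.warns(UserWarning):
            whiteness_test(e, M=5, n_shuffles=10, seed=0)


class TestUnivariateChi2:
    def test_matches_brute_force_autocorrelation_sum(self):
        rng = np.random.default_rng(8)
        e = rng.permutation(np.r_[np.ones(50), -np.ones(50)])
        stat, p = chi2_whiteness_univariate(e, 5)
        ec = e - e.mean()
        rho = [float(ec[i:] @ ec[:100 - i]) / float(ec @ ec)
               for i in range(1, 6)]
        assert stat == pytest.approx(100 * np.sum(np.square(rho)))
        assert 0 <= p <= 1

    def test_agrees_with_statsmodels_box_pierce(self):
        from statsmodels.stats.diagnostic import acorr_ljungbox
        e = np.random.default_rng(9).standard_normal(500)
        stat, p = chi2_whiteness_univariate(e, 10)
        table = acorr_ljungbox(e, lags=[10], boxpierce=True)
        assert stat == pytest.approx(float(table["bp_stat"].iloc[0]), rel=1e-6)
        assert p == pytest.approx(float(table["bp_pvalue"].iloc[0]), abs=1e-6)

    def test_p_values_uniform_under_null(self):
        ps = []
        for seed in range(200):
            e = np.random.default_rng(100 + seed).standard_normal(1000)
            ps.append(chi2_whiteness_univariate(e, 20)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_lags_is_trivially_white(self):
        assert chi2_whiteness_univariate(np.arange(10.0), 0) == (0.0, 1.0)

    def test_constant_residual_rejected(self):
        with pytest.raises(errors.DegenerateSignalError):
            chi2_whiteness_univariate(np.ones(50), 5)


class TestCVPlans:
    def test_train_and_test_are_disjoint_segments(self):
        recs = [Recording(np.random.default_rng(i).standard_normal((2, 100)))
                for i in range(3)]
        plan = build_cv_plan(recs, "fmri-like")
        assert len(plan) == 6
        for train, test in plan.folds:
            assert len(train) == 5
            assert all(tr is not test for tr in train)

    def test_ieeg_split_fractions(self):
        rec = Recording(np.random.default_rng(0).standard_normal((2, 1000)))
        plan = build_cv_plan(rec, "ieeg-like")
        (train, test), = plan.folds
        assert train[0].n_samples == 800 and test.n_samples == 200

    def test_too_short_recording_rejected(self):
        with pytest.raises(errors.InsufficientSamplesError):
            build_cv_plan(Recording(np.zeros((1, 3)) + np.arange(3)),
                          "fmri-like")


class TestSignedRank:
    def test_identical_scores_never_significant(self):
        x = np.random.default_rng(10).standard_normal(20)
        res = signed_rank_compare(np.vstack([x, x]))
        assert res.p_values[0, 1] == 1.0
        assert not res.significant.any()

    def test_five_positive_differences_exact_p(self):
        base = np.zeros(5)
        better = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        res = signed_rank_compare(np.vstack([better, base]))
        assert res.p_values[0, 1] == pytest.approx(1.0 / 32.0)

    def test_bh_step_up_textbook_example(self):
        from statsmodels.stats.multitest import multipletests
        pvals = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        rejected, *_ = multipletests(pvals, alpha=0.05, method="fdr_bh")
        # p_(k) <= k/5 * 0.05 holds for every k here: all discoveries
        assert rejected.all()

    def test_bh_mask_monotone_in_alpha(self):
        rng = np.random.default_rng(11)
        scores = rng.standard_normal((4, 30))
        scores[0] += 0.8
        strict = signed_rank_compare(scores, alpha=0.01)
        loose = signed_rank_compare(scores, alpha=0.10)
        assert not (strict.significant & ~loose.significant).any()

    def test_too_few_samples_rejected(self):
        with pytest.raises(errors.InsufficientSamplesError):
            signed_rank_compare(np.zeros((2, 4)))


@pytest.fixture(scope="module")
def plan():
    recs = [gen_stable_var(2, T=600, seed=s)[0] for s in (0, 1)]
    return build_cv_plan(recs, "fmri-like")


class TestEvaluateModel:

    def test_zero_model_rows_match_direct_formula(self, plan):
        table = evaluate_model("zero", {}, plan, seed=0, n_shuffles=20)
        assert len(table) == 2 * len(plan)
        train, test = plan.folds[0]
        from neurosysid.linear import predict_zero
        ps = predict_zero(test)
        direct = r2_per_channel(ps.actual(), ps.predictions).r2
        got = table[table["fold"] == 0]["r2"].to_numpy()
        np.testing.assert_allclose(got, direct)

    def test_model_on_demand_training_time_is_zero(self, plan):
        for family, params in (("manifold", {"h": 1.0}),
                               ("mmse", {"beta": 0.05})):
            table = evaluate_model(family, params, plan, seed=0,
                                   n_shuffles=20)
            assert (table["fit_time"] == 0.0).all()

    def test_unknown_family_rejected(self, plan):
        with pytest.raises(errors.InvalidParameterError):
            evaluate_model("oracle", {}, plan)
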