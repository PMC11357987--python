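"""Zero-order-hold baseline and linear first-difference (V)AR models."""
import numpy as np
import pytest

from neurosysid import errors
from neurosysid.datatypes import Recording
from neurosysid.evalstats import r2_per_channel
from neurosysid.linear import LinearARModel, fit_ar, predict_linear, predict_zero
from neurosysid.synthgen import gen_stable_var


class TestZeroModel:
    def test_holds_previous_sample(self):
        ps = predict_zero(Recording(np.array([[3.0, 5.0, 4.0]])))
        np.testing.assert_array_equal(ps.predictions, [[3.0, 5.0]])
        np.testing.assert_array_equal(ps.residuals, [[2.0, -1.0]])
        np.testing.assert_array_equal(ps.indices, [1, 2])

    def test_constant_series_has_zero_residuals(self):
        ps = predict_zero(Recording(np.full((2, 50), 1.5)))
        assert np.abs(ps.residuals).max() == 0.0

    def test_random_walk_residuals_recover_innovations(self):
        rng = np.random.default_rng(0)
        e = rng.standard_normal(500)
        y = np.cumsum(e)
        ps = predict_zero(Recording(y[None, :]))
        np.testing.assert_allclose(ps.residuals[0], e[1:])

    def test_single_sample_rejected(self):
        with pytest.raises(errors.InvalidParameterError):
            Recording(np.array([[1.0]]))


class TestFitAR:
    def test_scalar_structure_forces_diagonal_coupling(self):
        rec, _ = gen_stable_var(4, d=2, T=3000, seed=1)
        m = fit_ar(rec, d=2, structure="scalar")
        off = ~np.eye(4, dtype=bool)
        assert np.all(m.W[off] == 0.0)
        assert m.lag_coefs[0].shape == (4,)

    def test_huge_lasso_weight_collapses_to_zero_model(self):
        rec, _ = gen_stable_var(3, d=1, T=2000, seed=2)
        m = fit_ar(rec, d=1, structure="sparse", lam=1e6)
        assert np.abs(m.W).max() == 0.0

    def test_training_r2_at_least_zero_model(self):
        # least squares includes the zero model in its feasible set
        rec, _ = gen_stable_var(4, d=1, T=3000, seed=3)
        m = fit_ar(rec, d=1)
        fitted = r2_per_channel(*_scored(predict_linear(m, rec)))
        zero = r2_per_channel(*_scored(predict_zero(rec)))
        assert np.all(fitted.r2 + 1e-9 >= zero.r2)

    def test_training_sse_nonincreasing_in_order(self):
        rec, _ = gen_stable_var(3, d=1, T=4000, seed=4)
        sses = []
        for d in (1, 2, 3):
            m = fit_ar(rec, d=d, lag_mode="full")
            ps = predict_linear(m, rec)
            start = 3 - d  # score the common index range across orders
            sses.append(float((ps.residuals[:, start:] ** 2).sum()))
        assert sses[0] >= sses[1] >= sses[2]

    @pytest.mark.parametrize("kwargs", [
        {"lam": -1.0}, {"structure": "sparse", "lam": 0.0},
        {"structure": "banana"}, {"d": 0},
    ])
    def test_invalid_parameters(self, kwargs):
        rec, _ = gen_stable_var(2, d=1, T=500, seed=0)
        with pytest.raises(errors.InvalidParameterError):
            fit_ar(rec, **{"d": 1, **kwargs})

    def test_segments_shorter_than_order_rejected(self):
        rec = Recording(np.random.default_rng(0).standard_normal((2, 3)))
        with pytest.raises(errors.InsufficientSamplesError):
            fit_ar([rec], d=3)


class TestPredictLinear:
    def test_first_difference_arithmetic(self):
        # yhat = y + W y = 2 + (-0.5)*2 = 1
        m = LinearARModel(W=np.array([[-0.5]]), train_mean=np.zeros(1))
        ps = predict_linear(m, Recording(np.array([[2.0, 0.0]])))
        assert ps.predictions[0, 0] == pytest.approx(1.0)

    def test_zero_coefficients_reduce_to_zero_model(self):
        rec = Recording(np.random.default_rng(1).standard_normal((2, 100)))
        m = LinearARModel(W=np.zeros((2, 2)), train_mean=np.zeros(2))
        ps = predict_linear(m, rec)
        pz = predict_zero(rec)
        np.testing.assert_allclose(ps.predictions, pz.predictions)

    def test_channel_mismatch_rejected(self):
        m = LinearARModel(W=np.zeros((2, 2)))
        with pytest.raises(errors.InvalidParameterError):
            predict_linear(m, Recording(np.zeros((3, 10)) + np.arange(10)))


def _scored(ps):
    s = ps.scored
    return s.actual(), s.predictions
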