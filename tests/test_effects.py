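"""Linearizing-mechanism curves (reduced scales; the full-protocol versions
run in test_acceptance)."""
import numpy as np
import pytest

from neurosysid import effects as fx
from neurosysid import errors


@pytest.fixture(scope="module")
def small_spatial_curve():
    return fx.spatial_averaging_curve(n_ave_grid=(1, 5), T=1000, reps=5,
                                      seed=0)


def test_single_pair_shows_clear_nonlinearity(small_spatial_curve):
    assert small_spatial_curve.gap_mean[0] > 0.02


def test_averaging_shrinks_the_gap(small_spatial_curve):
    assert small_spatial_curve.gap_mean[1] < small_spatial_curve.gap_mean[0]


def test_curves_are_deterministic(small_spatial_curve):
    again = fx.spatial_averaging_curve(n_ave_grid=(1, 5), T=1000, reps=5,
                                       seed=0)
    np.testing.assert_array_equal(again.gap, small_spatial_curve.gap)


def test_r2_never_exceeds_one(small_spatial_curve):
    assert np.all(small_spatial_curve.r2_linear <= 1.0)
    assert np.all(small_spatial_curve.r2_nonlinear <= 1.0)


def test_unfiltered_white_pair_keeps_nonlinearity():
    curves = fx.temporal_averaging_curve(f_cutoff_grid=(1.0, 0.02),
                                         p_grid=(0.0,), T=1000, reps=5,
                                         seed=1)
    c = curves[0.0]
    assert c.gap_mean[0] > 0.02       # no filtering: tanh visible
    assert c.gap_mean[1] < c.gap_mean[0]  # strong filtering: linearized


def test_sphere_perfect_correlation_keeps_gap():
    curves = fx.sphere_averaging_curve(corr_length_grid=(np.inf,),
                                       n_ave_grid=(1, 10), T=1000, reps=5,
                                       seed=2)
    c = curves[float(np.inf)]
    # identical units: averaging cannot remove the sigmoid
    assert abs(c.gap_mean[1] - c.gap_mean[0]) < 2 * (c.gap_sem[0]
                                                     + c.gap_sem[1])
    assert c.gap_mean[1] > 0.02


def test_low_snr_masks_nonlinearity():
    curve = fx.snr_curve(snr_grid=(0.25, 100.0), T=1000, reps=5, seed=3)
    assert curve.gap_mean[0] < curve.gap_mean[1]
    assert curve.gap_mean[1] > 0.02


def test_one_dimensional_manifold_beats_linear():
    curve = fx.dimensionality_curve(n_grid=(1,), N=500, iters=3, seed=4)
    assert curve.gap_mean[0] > 0.05
    assert curve.optimal_h is not None


class TestGapThreshold:
    def _curve(self, grid, gaps):
        gaps = np.asarray(gaps, dtype=float)[:, None]
        z = np.zeros(len(grid))
        return fx.EffectCurve(np.asarray(grid, dtype=float), z, z, z, z,
                              gaps)

    def test_smallest_qualifying_grid_value(self):
        c = self._curve([1, 2, 5], [0.3, 0.1, 0.005])
        assert fx.gap_threshold(c, 0.01) == 5.0

    def test_largest_direction(self):
        c = self._curve([0.25, 1.0, 4.0], [0.001, 0.005, 0.3])
        assert fx.gap_threshold(c, 0.01, direction="largest") == 1.0

    def test_no_grid_point_qualifies(self):
        c = self._curve([1, 2], [0.5, 0.4])
        assert fx.gap_threshold(c, 0.01) is None

    def test_epsilon_above_every_gap_returns_first_value(self):
        c = self._curve([1, 2], [0.5, 0.4])
        assert fx.gap_threshold(c, 1.0) == 1.0

    def test_invalid_epsilon(self):
        c = self._curve([1], [0.1])
        with pytest.raises(errors.InvalidParameterError):
            fx.gap_threshold(c, 0.0)


def test_effect_curve_serializes_to_plain_types():
    c = fx.spatial_averaging_curve(n_ave_grid=(1,), T=500, reps=2, seed=5)
    d = c.to_dict()
    import json
    json.dumps(d)  # must be JSON-clean
    assert d["reps"] == 2 and len(d["grid"]) == 1
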