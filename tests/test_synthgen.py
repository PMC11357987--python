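"""Generator correctness: distributions, spectra, dynamics, spiking."""
import numpy as np
import pytest
from scipy import signal, stats

from neurosysid import errors
from neurosysid import synthgen as sg


@pytest.mark.parametrize("make", [
    lambda s: sg.gen_iid_tanh_ensemble(5, 200, s)[0].values,
    lambda s: sg.gen_sphere_correlated_ensemble(5, 0.5, 200, s)[0].values,
    lambda s: sg.gen_colored_signal(256, 2.0, s).values,
    lambda s: sg.gen_sum_tanh_dataset(3, 100, s)[0],
    lambda s: sg.gen_stable_var(3, T=500, seed=s)[0].values,
    lambda s: sg.simulate_izhikevich(
        sg.IzhikevichParams(input_noise_std=2.0), 3, 100.0, s)[0],
], ids=["iid_tanh", "sphere", "colored", "sum_tanh", "var", "izhikevich"])
def test_generators_are_pure_functions_of_seed(make):
    a, b = make(7), make(7)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, make(8))


class TestIidTanh:
    def test_pair_shapes_and_tanh_relation(self):
        xe, ye = sg.gen_iid_tanh_ensemble(5, 2000, 0)
        assert xe.values.shape == ye.values.shape == (5, 2000)
        assert xe.average.shape == (2000,)
        np.testing.assert_allclose(ye.values, np.tanh(xe.values))

    def test_single_unit_average_keeps_exact_sigmoid(self):
        xe, ye = sg.gen_iid_tanh_ensemble(1, 100, 1)
        np.testing.assert_allclose(ye.average, np.tanh(xe.average))

    @pytest.mark.parametrize("n_ave,T", [(0, 100), (5, 1)])
    def test_invalid_parameters(self, n_ave, T):
        with pytest.raises(errors.InvalidParameterError):
            sg.gen_iid_tanh_ensemble(n_ave, T, 0)


class TestSphereEnsemble:
    def test_infinite_correlation_length_gives_identical_units(self):
        xe, ye, _ = sg.gen_sphere_correlated_ensemble(6, np.inf, 500, 0)
        spread = np.abs(xe.values - xe.values[0]).max()
        assert spread < 1e-4
        np.testing.assert_allclose(ye.average, np.tanh(xe.average), atol=1e-4)

    def test_empirical_correlation_matches_distance_kernel(self):
        xe, _, pos = sg.gen_sphere_correlated_ensemble(50, 0.5, 5000, 3)
        emp = np.corrcoef(xe.values)
        dist = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        expected = np.exp(-dist / 0.5)
        off = ~np.eye(50, dtype=bool)
        assert np.abs(emp[off] - expected[off]).mean() < 0.05

    def test_short_correlation_length_recovers_independent_marginals(self):
        # pairwise correlations vanish and marginals stay standard normal
        xe, _, _ = sg.gen_sphere_correlated_ensemble(10, 1e-3, 5000, 4)
        emp = np.corrcoef(xe.values)
        off = ~np.eye(10, dtype=bool)
        assert np.abs(emp[off]).mean() < 0.05
        ks = stats.kstest(xe.values[0], "norm").statistic
        assert ks < 0.02

    def test_positions_inside_unit_ball(self):
        _, _, pos = sg.gen_sphere_correlated_ensemble(100, 1.0, 10, 0)
        assert np.all(np.linalg.norm(pos, axis=1) <= 1.0)


class TestGaussianLPF:
    def test_unit_cutoff_is_identity(self):
        x = np.random.default_rng(0).standard_normal(200)
        np.testing.assert_array_equal(sg.gaussian_lpf(x, 1.0), x)

    def test_constant_series_unchanged(self):
        x = np.full(100, 3.25)
        np.testing.assert_allclose(sg.gaussian_lpf(x, 0.1), x)

    def test_white_noise_variance_shrinks_by_kernel_energy(self):
        # the filtered series is strongly autocorrelated, so a single
        # T=1e4 variance-ratio estimate has ~12% sampling noise; average
        # over seeds to resolve the 5% oracle tolerance
        ratios = []
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal(10_000)
            ratios.append(sg.gaussian_lpf(x, 0.1).var() / x.var())
        taps = sg.gaussian_lpf_kernel(0.1)
        expected = float(np.sum(taps ** 2))  # independent oracle: sum k_j^2
        assert np.mean(ratios) == pytest.approx(expected, rel=0.05)

    @pytest.mark.parametrize("fc", [0.0, -0.5, 1.5])
    def test_invalid_cutoff(self, fc):
        with pytest.raises(errors.InvalidParameterError):
            sg.gaussian_lpf(np.zeros(10), fc)


class TestColoredSignal:
    @pytest.mark.parametrize("p,slope_tol", [(0.0, 0.15), (2.0, 0.25)])
    def test_log_periodogram_slope(self, p, slope_tol):
        slopes = []
        for seed in range(20):
            x = sg.gen_colored_signal(2 ** 14, p, seed).values[0]
            f, P = signal.welch(x, nperseg=2048)
            keep = f > 0
            slopes.append(np.polyfit(np.log(f[keep]), np.log(P[keep]), 1)[0])
        assert np.mean(slopes) == pytest.approx(-p, abs=slope_tol)

    def test_unit_variance(self):
        for p in (0.0, 1.0, 3.0):
            x = sg.gen_colored_signal(1024, p, 0).values[0]
            assert x.var() == pytest.approx(1.0, abs=0.05)

    def test_too_short_rejected(self):
        with pytest.raises(errors.InvalidParameterError):
            sg.gen_colored_signal(32, 1.0, 0)


class TestNoiseAtSNR:
    def test_empirical_variance_ratio(self):
        x = np.random.default_rng(2).standard_normal(10_000)
        noisy = sg.add_noise_at_snr(x, sg.NoiseSpec(1.0), 5)
        ratio = (noisy - x).var() / x.var()
        assert 0.9 < ratio < 1.1

    def test_constant_series_rejected(self):
        with pytest.raises(errors.DegenerateSignalError):
            sg.add_noise_at_snr(np.ones(100), sg.NoiseSpec(4.0), 0)

    def test_invalid_snr(self):
        with pytest.raises(errors.InvalidParameterError):
            sg.NoiseSpec(0.0)


class TestSumTanh:
    def test_single_dimension_is_plain_tanh(self):
        X, y = sg.gen_sum_tanh_dataset(1, 50, 0)
        np.testing.assert_allclose(y, np.tanh(X[:, 0]))

    def test_shapes(self):
        X, y = sg.gen_sum_tanh_dataset(40, 1000, 0)
        assert X.shape == (1000, 40) and y.shape == (1000,)

    def test_row_sum_variance_scales_with_dimension(self):
        X, _ = sg.gen_sum_tanh_dataset(10, 10_000, 1)
        assert X.sum(axis=1).var() == pytest.approx(10.0, rel=0.1)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(errors.InvalidParameterError):
            sg.gen_sum_tanh_dataset(10, 11, 0)


class TestStableVAR:
    def test_spectral_radius_respected(self):
        for d in (1, 3):
            _, truth = sg.gen_stable_var(4, d=d, T=2000,
                                         spectral_radius_target=0.9, seed=0)
            radius = max(abs(np.linalg.eigvals(truth.companion())))
            assert radius <= 0.9 + 1e-9

    def test_stationary_covariance_matches_lyapunov_solution(self):
        from scipy.linalg import solve_discrete_lyapunov
        rec, truth = sg.gen_stable_var(3, d=1, T=100_000, noise_std=1.0,
                                       seed=2)
        A = truth.companion()
        P = solve_discrete_lyapunov(A, np.eye(3))
        emp = rec.values @ rec.values.T / rec.n_samples
        assert (np.linalg.norm(emp - P) / np.linalg.norm(P)) < 0.05

    def test_zero_density_rejected_as_nonstationary(self):
        with pytest.raises(errors.InvalidParameterError):
            sg.gen_stable_var(3, d=1, density=0.0, T=1000, seed=0)


class TestIzhikevich:
    def test_rest_state_is_exact_fixed_point(self):
        # v = -70, u = b v solves 0.04 v^2 + 5v + 140 - u + 0 = 0
        p = sg.IzhikevichParams(I=0.0, v0=-70.0)
        V, spikes = sg.simulate_izhikevich(p, 2, 50.0, 0)
        assert np.abs(V + 70.0).max() == 0.0
        assert all(len(s) == 0 for s in spikes)

    def test_spike_count_matches_independent_euler_loop(self):
        p = sg.IzhikevichParams()  # a=.02 b=.2 c=-65 d=2 I=7
        _, spikes = sg.simulate_izhikevich(p, 1, 1000.0, 0)
        # independent plain-python reference integration
        v, u = p.v0, p.b * p.v0
        count = 0
        for _ in range(10_000):
            v, u = (v + 0.1 * (0.04 * v * v + 5 * v + 140 - u + 7.0),
                    u + 0.1 * 0.02 * (0.2 * v - u))
            if v >= 30.0:
                count += 1
                v, u = -65.0, u + 2.0
        assert len(spikes[0]) == count > 0

    def test_reset_prevents_consecutive_suprathreshold_samples(self):
        p = sg.IzhikevichParams(input_noise_std=3.0)
        V, _ = sg.simulate_izhikevich(p, 3, 500.0, 1)
        above = V >= 30.0
        assert not np.any(above[:, :-1] & above[:, 1:])

    def test_too_short_duration_rejected(self):
        with pytest.raises(errors.InvalidParameterError):
            sg.simulate_izhikevich(sg.IzhikevichParams(), 1, 0.5, 0)
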