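"""Synthetic signal generators with known ground truth.

Every generator is a pure function of its parameters and an integer seed:
identical calls return bit-identical arrays. The ensembles emulate the
building blocks of the linearizing-mechanism experiments — independent
sigmoidal (tanh) unit pairs, distance-correlated Gaussian fields on the unit
ball, power-law (1/f^p) colored signals, additive observation noise at a
prescribed SNR, stable sparse first-difference VAR dynamics, and uncoupled
Izhikevich spiking neurons integrated by Euler at 0.1 ms.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.linalg import cholesky

from .datatypes import Recording
from .errors import (DegenerateSignalError, IntegrationFailureError,
                     InvalidParameterError, NumericalDegeneracyError)

__all__ = [
    "SignalEnsemble", "GroundTruthVAR", "IzhikevichParams", "NoiseSpec",
    "gen_iid_tanh_ensemble", "gen_sphere_correlated_ensemble", "gaussian_lpf",
    "gen_colored_signal", "add_noise_at_snr", "gen_sum_tanh_dataset",
    "gen_stable_var", "simulate_izhikevich", "companion_matrix",
]


@dataclass
class SignalEnsemble:
    """A units x time matrix plus the parameters that generated it."""

    values: np.ndarray  # (units, T)
    kind: str
    params: dict
    seed: int

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("ensemble values must be finite")
        if self.values.shape[1] < 2 or self.values.shape[0] < 1:
            raise InvalidParameterError("ensemble needs >= 1 unit and >= 2 samples")

    @property
    def average(self) -> np.ndarray:
        """Arithmetic mean over units at each time point."""
        return self.values.mean(axis=0)


@dataclass
class GroundTruthVAR:
    """Ground-truth coefficients of a stable first-difference (V)AR process.

    The dynamics are ``y(t) - y(t-1) = W y(t-1) + sum_p D_p y(t-p) + e(t)``
    with ``e(t)`` iid Gaussian; ``W`` is the effective-connectivity drift.
    """

    W: np.ndarray
    lag_diagonals: list[np.ndarray] = field(default_factory=list)
    noise_std: float = 1.0
    spectral_radius_target: float = 0.9

    @property
    def order(self) -> int:
        return 1 + len(self.lag_diagonals)

    def companion(self) -> np.ndarray:
        n = self.W.shape[0]
        mats = [np.eye(n) + self.W]
        mats += [np.diag(d) for d in self.lag_diagonals]
        return companion_matrix(mats)


@dataclass
class IzhikevichParams:
    """Constants of the planar quadratic integrate-and-fire (Izhikevich) model.

    ``v`` is the membrane potential (mV), ``u`` the recovery variable; on
    ``v >= 30`` mV a spike is recorded and ``(v, u) <- (c, u + d)``.
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 2.0
    I: float = 7.0
    dt: float = 0.1  # ms
    v_reset_threshold: float = 30.0
    input_noise_std: float = 0.0
    v0: float = -70.0
    u0: float | None = None  # default b*v0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise InvalidParameterError("dt must be positive")
        if self.input_noise_std < 0:
            raise InvalidParameterError("input_noise_std must be nonnegative")
        if self.u0 is None:
            self.u0 = self.b * self.v0


@dataclass
class NoiseSpec:
    """Additive zero-mean Gaussian observation noise at a variance-ratio SNR."""

    snr: float

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise InvalidParameterError("snr must be positive")


# ---------------------------------------------------------------------------
# static sigmoidal ensembles


def gen_iid_tanh_ensemble(n_ave: int, T: int, seed: int
                          ) -> tuple[SignalEnsemble, SignalEnsemble]:
    """``n_ave`` iid standard-normal unit series x_i(t) and y_i = tanh(x_i).

    Returns the (x, y) ensemble pair; unit averages are available as
    ``ensemble.average``.
    """
    if n_ave < 1 or T < 2:
        raise InvalidParameterError("n_ave must be >= 1 and T >= 2")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_ave, T))
    params = {"n_ave": n_ave, "T": T}
    return (SignalEnsemble(x, "iid_tanh", params, seed),
            SignalEnsemble(np.tanh(x), "iid_tanh", params, seed))


def gen_sphere_correlated_ensemble(n_ave: int, corr_length: float, T: int,
                                   seed: int
                                   ) -> tuple[SignalEnsemble, SignalEnsemble,
                                              np.ndarray]:
    """Unit pairs at random positions in the unit ball with
    ``corr(x_i, x_j) = exp(-dist_ij / corr_length)`` and y = tanh(x).

    ``corr_length`` may be ``np.inf`` (all units perfectly correlated).
    Returns (x ensemble, y ensemble, positions (n_ave, 3)).
    """
    if n_ave < 1 or T < 2:
        raise InvalidParameterError("n_ave must be >= 1 and T >= 2")
    if not corr_length > 0:
        raise InvalidParameterError("corr_length must be positive")
    rng = np.random.default_rng(seed)
    # uniform in the unit ball: random direction, radius ~ U^(1/3)
    direction = rng.standard_normal((n_ave, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    pos = direction * rng.uniform(size=(n_ave, 1)) ** (1.0 / 3.0)
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    if np.isinf(corr_length):
        corr = np.ones_like(dist)
    else:
        corr = np.exp(-dist / corr_length)
    L = _jittered_cholesky(corr)
    x = L @ rng.standard_normal((n_ave, T))
    params = {"n_ave": n_ave, "corr_length": corr_length, "T": T}
    return (SignalEnsemble(x, "sphere", params, seed),
            SignalEnsemble(np.tanh(x), "sphere", params, seed),
            pos)


def _jittered_cholesky(corr: np.ndarray) -> np.ndarray:
    jitter = 0.0
    for _ in range(8):
        try:
            return cholesky(corr + jitter * np.eye(corr.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            pass
        except Exception:
            pass
        jitter = 1e-12 if jitter == 0.0 else jitter * 10.0
        if jitter > 1e-4:
            break
    raise NumericalDegeneracyError(
        "correlation matrix could not be factorized after jitter escalation")


# ---------------------------------------------------------------------------
# temporal averaging / coloring


def gaussian_lpf(series: np.ndarray, f_cutoff: float) -> np.ndarray:
    """Gaussian low-pass filter along the time (last) axis.

    ``f_cutoff`` is normalized to the Nyquist frequency; 1 means no
    filtering. The kernel is a unit-sum discrete Gaussian of standard
    deviation ``sigma_t = 1/f_cutoff - 1`` samples, truncated at +/- 4 sigma,
    applied with reflective boundaries.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 2:
        raise InvalidParameterError("series must have length >= 2")
    if not (0 < f_cutoff <= 1):
        raise InvalidParameterError("f_cutoff must lie in (0, 1]")
    sigma = 1.0 / f_cutoff - 1.0
    if sigma == 0.0:
        return series.copy()
    radius = max(1, int(math.ceil(4.0 * sigma)))
    taps = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
    taps /= taps.sum()
    return ndimage.convolve1d(series, taps, axis=-1, mode="reflect")


def gaussian_lpf_kernel(f_cutoff: float) -> np.ndarray:
    """The unit-sum kernel taps used by :func:`gaussian_lpf`."""
    if not (0 < f_cutoff <= 1):
        raise InvalidParameterError("f_cutoff must lie in (0, 1]")
    sigma = 1.0 / f_cutoff - 1.0
    if sigma == 0.0:
        return np.array([1.0])
    radius = max(1, int(math.ceil(4.0 * sigma)))
    taps = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
    return taps / taps.sum()


def gen_colored_signal(T: int, p: float, seed: int) -> SignalEnsemble:
    """A unit-variance signal with power-law PSD decaying like ``f^-p``.

    Spectral synthesis: rFFT amplitudes proportional to ``(1 + k)^(-p/2)``
    (``k`` the integer frequency-bin index, so the DC amplitude is finite),
    uniform random phases, inverse transform, then normalization to unit
    sample variance.
    """
    if T < 64:
        raise InvalidParameterError("T must be >= 64")
    if p < 0:
        raise InvalidParameterError("p must be nonnegative")
    rng = np.random.default_rng(seed)
    k = np.arange(T // 2 + 1)
    amp = (1.0 + k) ** (-p / 2.0)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=k.size)
    spec = amp * np.exp(1j * phase)
    spec[0] = 0.0  # zero mean
    if T % 2 == 0:
        spec[-1] = amp[-1] * np.cos(phase[-1])  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=T)
    x /= x.std()
    return SignalEnsemble(x[None, :], "colored", {"T": T, "p": p}, seed)


# ---------------------------------------------------------------------------
# observation noise


def add_noise_at_snr(series: np.ndarray, spec: NoiseSpec, seed: int
                     ) -> np.ndarray:
    """Add independent zero-mean Gaussian noise with variance
    ``var(series) / snr`` (SNR as a variance ratio)."""
    series = np.asarray(series, dtype=float)
    var = series.var()
    if var == 0:
        raise DegenerateSignalError("cannot set an SNR on a zero-variance series")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(series.shape) * math.sqrt(var / spec.snr)
    return series + noise


# ---------------------------------------------------------------------------
# high-dimensional one-dimensional nonlinearity


def gen_sum_tanh_dataset(n: int, N: int, seed: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """N samples of n iid standard-normal predictors with response
    ``y = tanh(x_1 + ... + x_n)`` (noise-free)."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if N <= n + 1:
        raise InvalidParameterError(f"need N > n+1 samples (got N={N}, n={n})")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((N, n))
    return X, np.tanh(X.sum(axis=1))


# ---------------------------------------------------------------------------
# ground-truth linear dynamics


def companion_matrix(coef_mats: list[np.ndarray]) -> np.ndarray:
    """Companion form of ``y(t) = A_1 y(t-1) + ... + A_d y(t-d)``."""
    d = len(coef_mats)
    n = coef_mats[0].shape[0]
    C = np.zeros((n * d, n * d))
    C[:n, :] = np.hstack(coef_mats)
    if d > 1:
        C[n:, :-n] = np.eye(n * (d - 1))
    return C


def gen_stable_var(n: int, d: int = 1, density: float = 0.5,
                   spectral_radius_target: float = 0.9, T: int = 2000,
                   noise_std: float = 1.0, seed: int = 0,
                   sampling_interval: float = 1.0
                   ) -> tuple[Recording, GroundTruthVAR]:
    """Simulate a stable sparse first-difference (V)AR with known coefficients.

    A random sparse drift W (lag 1) and diagonal higher-lag coefficients are
    rescaled so the companion matrix of the implied lag polynomial has
    spectral radius <= ``spectral_radius_target``; the process is simulated
    with iid Gaussian noise after a discarded burn-in of ``10 n`` samples.
    """
    if n < 1 or d < 1:
        raise InvalidParameterError("n and d must be >= 1")
    if not (0 < density <= 1):
        raise InvalidParameterError(
            "density must lie in (0, 1]: density 0 with d=1 is a random walk "
            "(nonstationary)")
    if not (0 < spectral_radius_target < 1):
        raise InvalidParameterError("spectral_radius_target must lie in (0, 1)")
    if T <= 10 * n * d:
        raise InvalidParameterError("T must exceed 10*n*d")
    rng = np.random.default_rng(seed)
    mask = rng.uniform(size=(n, n)) < density
    W = rng.standard_normal((n, n)) * mask * 0.5
    lag_diags = [rng.standard_normal(n) * 0.2 for _ in range(d - 1)]

    # scale A_p by gamma^p: companion eigenvalues scale linearly by gamma
    mats = [np.eye(n) + W] + [np.diag(v) for v in lag_diags]
    radius = max(abs(np.linalg.eigvals(companion_matrix(mats))))
    if radius > spectral_radius_target:
        gamma = spectral_radius_target / radius
        mats = [m * gamma ** (p + 1) for p, m in enumerate(mats)]
    W = mats[0] - np.eye(n)
    lag_diags = [np.diag(m).copy() for m in mats[1:]]

    truth = GroundTruthVAR(W, lag_diags, noise_std, spectral_radius_target)
    burn = 10 * n
    total = T + burn + d
    y = np.zeros((n, total))
    noise = rng.standard_normal((n, total)) * noise_std
    for t in range(d, total):
        acc = mats[0] @ y[:, t - 1]
        for p in range(1, d):
            acc += mats[p] @ y[:, t - p - 1]
        y[:, t] = acc + noise[:, t]
    rec = Recording(y[:, burn + d:], sampling_interval)
    return rec, truth


# ---------------------------------------------------------------------------
# Izhikevich spiking neurons


def simulate_izhikevich(params: IzhikevichParams, n_neurons: int,
                        duration_ms: float, seed: int
                        ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Euler-integrate ``n_neurons`` uncoupled Izhikevich neurons.

    Dynamics per neuron: ``dv/dt = 0.04 v^2 + 5 v + 140 - u + I (+ noise)``,
    ``du/dt = a (b v - u)``; on ``v >= 30`` a spike is recorded, the sample
    is clamped at 30 mV and ``(v, u) <- (c, u + d)`` before the next step.
    Input noise is iid Gaussian current noise per neuron and step.

    Returns (membrane potentials (n_neurons, n_steps), spike times in ms per
    neuron).
    """
    if n_neurons < 1:
        raise InvalidParameterError("n_neurons must be >= 1")
    if duration_ms < 10 * params.dt:
        raise InvalidParameterError("duration_ms must be >= 10 dt")
    rng = np.random.default_rng(seed)
    dt = params.dt
    n_steps = int(round(duration_ms / dt))
    v = np.full(n_neurons, params.v0, dtype=float)
    u = np.full(n_neurons, float(params.u0), dtype=float)
    V = np.empty((n_neurons, n_steps))
    spikes: list[list[float]] = [[] for _ in range(n_neurons)]
    for step in range(n_steps):
        I = params.I
        if params.input_noise_std > 0:
            I = I + params.input_noise_std * rng.standard_normal(n_neurons)
        dv = 0.04 * v * v + 5.0 * v + 140.0 - u + I
        du = params.a * (params.b * v - u)
        v = v + dt * dv
        u = u + dt * du
        if not np.all(np.isfinite(v)):
            raise IntegrationFailureError(
                f"membrane potential blew up at step {step}", step=step)
        fired = v >= params.v_reset_threshold
        if np.any(fired):
            t_ms = (step + 1) * dt
            for i in np.flatnonzero(fired):
                spikes[i].append(t_ms)
            v = np.where(fired, params.v_reset_threshold, v)
            V[:, step] = v
            v = np.where(fired, params.c, v)
            u = np.where(fired, u + params.d, u)
        else:
            V[:, step] = v
    return V, [np.asarray(s) for s in spikes]
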