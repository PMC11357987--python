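"""Stochastic subspace identification with a steady-state Kalman predictor.

Fits the innovation-form state-space model

    x(t+1) = A x(t) + w(t)         A = I + W  (first-difference drift)
    y(t)   = C x(t) + v(t)         Cov[w; v] = [[Q, M], [M', R]]

by covariance-based stochastic realization: the block-Hankel matrix of
output covariances (r future by s past block rows) is factorized by a
truncated SVD into observability and controllability factors, A follows from
shift invariance, and the steady-state one-step predictor gain K comes from
iterating the forward Riccati recursion to tolerance. Predictions are run
through the stationary predictor ``xhat(t+1) = (A - K C) xhat(t) + K y(t)``.
"""
from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .datatypes import PredictionSet, Recording
from .errors import (InsufficientSamplesError, InvalidParameterError,
                     NumericalDegeneracyError)

__all__ = ["SubspaceModel", "fit_subspace", "predict_subspace"]


@dataclass
class SubspaceModel:
    A: np.ndarray            # state transition (n_x, n_x)
    C: np.ndarray            # output matrix (n, n_x)
    K: np.ndarray            # steady-state predictor gain (n_x, n)
    Q: np.ndarray            # innovation-form process noise covariance
    M: np.ndarray            # process/observation noise cross-covariance
    R: np.ndarray            # innovation covariance
    n_x: int = 1
    r: int = 2               # future block rows
    s: int = 2               # past block rows
    train_mean: np.ndarray | None = None
    fit_time: float = 0.0

    @property
    def predictor_matrix(self) -> np.ndarray:
        return self.A - self.K @ self.C

    @property
    def predictor_spectral_radius(self) -> float:
        return float(max(abs(np.linalg.eigvals(self.predictor_matrix))))


def _output_covariances(segments: list[np.ndarray], max_lag: int
                        ) -> list[np.ndarray]:
    """Biased lagged output covariance estimates pooled over segments."""
    n = segments[0].shape[0]
    cov = [np.zeros((n, n)) for _ in range(max_lag + 1)]
    counts = np.zeros(max_lag + 1)
    for y in segments:
        N = y.shape[1]
        for lag in range(max_lag + 1):
            if N <= lag:
                continue
            cov[lag] += y[:, lag:] @ y[:, :N - lag].T
            counts[lag] += N - lag
    return [c / max(k, 1) for c, k in zip(cov, counts)]


def fit_subspace(train: Recording | list[Recording], n_x: int,
                 r: int = 5, s: int = 5, riccati_tol: float = 1e-10,
                 riccati_max_iter: int = 10_000) -> SubspaceModel:
    """Covariance-based stochastic subspace identification of order ``n_x``."""
    segs = [train] if isinstance(train, Recording) else list(train)
    n = segs[0].n_channels
    if n_x < 1:
        raise InvalidParameterError("n_x must be >= 1")
    if n_x > r * n:
        raise InvalidParameterError(
            f"n_x={n_x} exceeds the rank bound r*n={r * n}")
    total = sum(seg.n_samples for seg in segs)
    if total < 10 * (r + s):
        raise InsufficientSamplesError(
            f"need >= {10 * (r + s)} training samples, got {total}")
    t0 = time.perf_counter()
    pooled = np.hstack([seg.values for seg in segs])
    train_mean = pooled.mean(axis=1)
    centered = [seg.values - train_mean[:, None] for seg in segs]

    lam = _output_covariances(centered, r + s)
    # block Hankel of future-past covariances: H[i, j] = Lambda_{i+j+1}
    H = np.block([[lam[i + j + 1] for j in range(s)] for i in range(r)])
    U, sv, Vt = np.linalg.svd(H, full_matrices=False)
    rank = int(np.sum(sv > sv[0] * 1e-10)) if sv[0] > 0 else 0
    if n_x > rank:
        raise NumericalDegeneracyError(
            f"requested n_x={n_x} exceeds the numerical rank {rank} of the "
            "covariance Hankel matrix")
    sqrt_sv = np.sqrt(sv[:n_x])
    gamma = U[:, :n_x] * sqrt_sv          # observability, (r*n, n_x)
    delta = sqrt_sv[:, None] * Vt[:n_x]   # controllability of (A, G)
    C = gamma[:n]
    G = delta[:, :n]                       # E[x(t+1) y(t)^T]
    if r > 1:
        A, *_ = np.linalg.lstsq(gamma[:-n], gamma[n:], rcond=None)
    else:
        # no shift rows available; fall back to controllability shift
        A, *_ = np.linalg.lstsq(delta[:, :-n].T, delta[:, n:].T, rcond=None)
        A = A.T
    lam0 = lam[0]

    # forward Riccati recursion for the state-prediction covariance P
    P = np.zeros((n_x, n_x))
    for _ in range(riccati_max_iter):
        innov_cov = lam0 - C @ P @ C.T
        try:
            gain = np.linalg.solve(innov_cov.T, (G - A @ P @ C.T).T).T
        except np.linalg.LinAlgError as exc:
            raise NumericalDegeneracyError(
                "singular innovation covariance in Riccati recursion") from exc
        P_next = A @ P @ A.T + gain @ innov_cov @ gain.T
        if np.max(np.abs(P_next - P)) < riccati_tol:
            P = P_next
            break
        P = P_next
    else:
        raise NumericalDegeneracyError(
            f"Riccati recursion did not converge in {riccati_max_iter} iterations")
    innov_cov = lam0 - C @ P @ C.T
    K = np.linalg.solve(innov_cov.T, (G - A @ P @ C.T).T).T
    model = SubspaceModel(A=A, C=C, K=K, Q=K @ innov_cov @ K.T,
                          M=K @ innov_cov, R=innov_cov, n_x=n_x, r=r, s=s,
                          train_mean=train_mean,
                          fit_time=time.perf_counter() - t0)
    if model.predictor_spectral_radius >= 1.0:
        raise NumericalDegeneracyError(
            "identified predictor is unstable "
            f"(spectral radius {model.predictor_spectral_radius:.3f})")
    return model


def predict_subspace(model: SubspaceModel, test: Recording) -> PredictionSet:
    """Run the steady-state predictor filter from zero initial state.

    The first ``max(r, s)`` predictions are flagged as burn-in (excluded from
    scoring by default via ``PredictionSet.burn_in``).
    """
    if test.n_samples < 2:
        raise InsufficientSamplesError("test segment needs >= 2 samples")
    if test.n_channels != model.C.shape[0]:
        raise InvalidParameterError("channel count mismatch with fitted model")
    if model.predictor_spectral_radius >= 1.0:
        raise NumericalDegeneracyError(
            "refusing to run an unstable predictor "
            f"(spectral radius {model.predictor_spectral_radius:.3f})")
    t0 = time.perf_counter()
    mean = (model.train_mean if model.train_mean is not None
            else np.zeros(test.n_channels))
    yc = test.values - mean[:, None]
    N = test.n_samples
    F = model.predictor_matrix
    x = np.zeros(model.n_x)
    pred = np.empty((test.n_channels, N - 1))
    for t in range(1, N):
        x = F @ x + model.K @ yc[:, t - 1]
        pred[:, t - 1] = model.C @ x
    pred += mean[:, None]
    indices = np.arange(1, N)
    burn = min(max(model.r, model.s), N - 2)
    return PredictionSet.from_actual(test.values[:, 1:], pred, indices,
                                     fit_time=model.fit_time,
                                     predict_time=time.perf_counter() - t0,
                                     burn_in=burn)
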