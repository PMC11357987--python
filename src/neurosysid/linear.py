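"""Linear first-difference (V)AR predictors and the zero-order-hold baseline.

The model class is ``y(t) - y(t-1) = W y(t-1) + D_2 y(t-2) + ... + D_d y(t-d)
+ e(t)`` where ``W`` is the effective-connectivity drift. Structures:

- ``dense``: unregularized least squares, full W (and full lag matrices in
  ``lag_mode='full'`` VAR form);
- ``sparse``: 1-norm (LASSO) regularization with weight ``lam > 0``;
- ``scalar``: W and every lag matrix diagonal — n decoupled scalar AR models.

Channels are mean-centered per training segment; the pooled training mean is
stored and reapplied at prediction so the constant-predictor baseline of R^2
stays coherent. Lags never cross segment boundaries.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso

from .datatypes import PredictionSet, Recording
from .errors import (InsufficientSamplesError, InvalidParameterError)

__all__ = ["LinearARModel", "predict_zero", "fit_ar", "predict_linear"]


@dataclass
class LinearARModel:
    """Fitted first-difference (V)AR coefficients.

    ``lag_coefs[p-2]`` holds the lag-p coefficient: an ``(n,)`` diagonal
    vector when ``lag_mode='diagonal'`` (AR) or an ``(n, n)`` matrix when
    ``lag_mode='full'`` (VAR).
    """

    W: np.ndarray
    lag_coefs: list[np.ndarray] = field(default_factory=list)
    order: int = 1
    structure: str = "dense"
    lag_mode: str = "diagonal"
    lam: float = 0.0
    train_mean: np.ndarray | None = None
    fit_time: float = 0.0

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    def lag_matrix(self, p: int) -> np.ndarray:
        """The lag-p coefficient as an (n, n) matrix (p >= 2)."""
        c = self.lag_coefs[p - 2]
        return np.diag(c) if c.ndim == 1 else c


def predict_zero(test: Recording) -> PredictionSet:
    """Zero-order-hold baseline: ``yhat(t|t-1) = y(t-1)`` for t >= 1."""
    y = test.values
    if y.shape[1] < 2:
        raise InsufficientSamplesError("zero model needs >= 2 samples")
    t0 = time.perf_counter()
    pred = y[:, :-1]
    indices = np.arange(1, y.shape[1])
    return PredictionSet.from_actual(y[:, 1:], pred, indices,
                                     predict_time=time.perf_counter() - t0)


def _segments(train: Recording | list[Recording]) -> list[Recording]:
    return [train] if isinstance(train, Recording) else list(train)


def _design(y: np.ndarray, d: int, lag_mode: str, channel: int | None = None
            ) -> tuple[np.ndarray, np.ndarray]:
    """Rows t = d..N-1 of the regression target dy(t) and regressors.

    Full regressor layout: [y(t-1) (n cols)] + per lag p=2..d either the own
    channel's y(t-p) (diagonal mode, built per channel) or all n channels
    (full mode). ``channel`` selects the target channel in diagonal/scalar
    builds.
    """
    n, N = y.shape
    t = np.arange(d, N)
    dy = (y[:, t] - y[:, t - 1]).T  # (rows, n)
    blocks = [y[:, t - 1].T]
    for p in range(2, d + 1):
        if lag_mode == "full":
            blocks.append(y[:, t - p].T)
        else:
            assert channel is not None
            blocks.append(y[channel, t - p][:, None])
    return np.hstack(blocks), dy


def fit_ar(train: Recording | list[Recording], d: int = 1,
           structure: str = "dense", lag_mode: str = "diagonal",
           lam: float = 0.0) -> LinearARModel:
    """Least-squares / LASSO fit of the first-difference (V)AR model.

    Each training segment is mean-centered by its own channel means before
    the regression rows are built; the pooled training mean is stored on the
    model for prediction.
    """
    segs = _segments(train)
    if d < 1:
        raise InvalidParameterError("order d must be >= 1")
    if lam < 0:
        raise InvalidParameterError("lam must be nonnegative")
    if structure not in ("dense", "sparse", "scalar"):
        raise InvalidParameterError(f"unknown structure {structure!r}")
    if lag_mode not in ("diagonal", "full"):
        raise InvalidParameterError(f"unknown lag_mode {lag_mode!r}")
    if structure == "sparse" and lam <= 0:
        raise InvalidParameterError("sparse structure requires lam > 0")
    if any(s.n_samples <= d for s in segs):
        raise InsufficientSamplesError(
            f"every training segment must be longer than d={d}")
    t0 = time.perf_counter()
    n = segs[0].n_channels
    pooled = np.hstack([s.values for s in segs])
    train_mean = pooled.mean(axis=1)
    centered = [s.values - s.values.mean(axis=1, keepdims=True) for s in segs]

    W = np.zeros((n, n))
    if lag_mode == "full":
        lag_coefs = [np.zeros((n, n)) for _ in range(d - 1)]
    else:
        lag_coefs = [np.zeros(n) for _ in range(d - 1)]

    for i in range(n):
        if structure == "scalar":
            X = np.vstack([np.column_stack([y[i, np.arange(d, y.shape[1]) - p]
                                            for p in range(1, d + 1)])
                           for y in centered])
            rows = np.concatenate([(y[i, d:] - y[i, d - 1:-1]) for y in centered])
            coef = _solve(X, rows, structure, lam)
            W[i, i] = coef[0]
            for p in range(2, d + 1):
                lag_coefs[p - 2][i] = coef[p - 1]
            continue
        if lag_mode == "full":
            Xs, dys = zip(*[_design(y, d, "full") for y in centered])
            X, dy = np.vstack(Xs), np.vstack(dys)[:, i]
        else:
            Xs, dys = zip(*[_design(y, d, "diagonal", channel=i)
                            for y in centered])
            X, dy = np.vstack(Xs), np.vstack(dys)[:, i]
        coef = _solve(X, dy, structure, lam)
        W[i] = coef[:n]
        if lag_mode == "full":
            for p in range(2, d + 1):
                lag_coefs[p - 2][i] = coef[n * (p - 1):n * p]
        else:
            for p in range(2, d + 1):
                lag_coefs[p - 2][i] = coef[n + p - 2]

    return LinearARModel(W, list(lag_coefs), d, structure, lag_mode, lam,
                         train_mean, fit_time=time.perf_counter() - t0)


def _solve(X: np.ndarray, y: np.ndarray, structure: str, lam: float
           ) -> np.ndarray:
    if structure == "sparse":
        # our objective sum(r^2) + lam*sum|w|; sklearn's is
        # (1/2m)||r||^2 + alpha*||w||_1  =>  alpha = lam / (2 m)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        model = Lasso(alpha=lam / (2.0 * X.shape[0]), fit_intercept=False,
                      max_iter=5000)
        model.fit(X / scale, y)
        return model.coef_ / scale
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def predict_linear(model: LinearARModel, test: Recording) -> PredictionSet:
    """One-step-ahead predictions of a fitted linear model on a test segment.

    ``yhat(t|t-1) = y(t-1) + W y(t-1) + sum_p D_p y(t-p)`` (on centered
    data), emitted for t = d..N-1 only so lags never leave the segment.
    """
    if test.n_channels != model.n_channels:
        raise InvalidParameterError(
            f"model has {model.n_channels} channels, test has {test.n_channels}")
    d = model.order
    if test.n_samples <= d:
        raise InsufficientSamplesError("test segment shorter than model order")
    t0 = time.perf_counter()
    mean = (model.train_mean if model.train_mean is not None
            else np.zeros(model.n_channels))
    yc = test.values - mean[:, None]
    t = np.arange(d, test.n_samples)
    delta = model.W @ yc[:, t - 1]
    for p in range(2, d + 1):
        delta += model.lag_matrix(p) @ yc[:, t - p]
    pred = test.values[:, t - 1] + delta
    return PredictionSet.from_actual(test.values[:, t], pred, t,
                                     fit_time=model.fit_time,
                                     predict_time=time.perf_counter() - t0)
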