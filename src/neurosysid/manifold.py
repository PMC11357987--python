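"""Locally linear (model-on-demand) prediction by order-1 local polynomials.

For each query point the regression surface is approximated by a tangent
hyperplane fitted by weighted least squares, with Gaussian distance weights
``k = exp(-||x_m - x_q||^2 / 2 h^2)`` over all training points. Only the
local intercept is used for prediction, which equals the fitted hyperplane
evaluated at the query. The bandwidth ``h`` controls how local or global the
model is: ``h -> infinity`` recovers a single global linear fit. There is no
training phase — the full training set is consulted at every query.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .datatypes import PredictionSet, Recording
from .errors import InsufficientSamplesError, InvalidParameterError

__all__ = ["ManifoldConfig", "local_linear_predict", "manifold_predict"]

logger = logging.getLogger(__name__)

PINV_RCOND = 1e-10  # relative singular-value truncation in the weighted LS


@dataclass
class ManifoldConfig:
    """Bandwidth ``h`` of the Gaussian kernel and number of own-lags ``d``
    stacked into the query vector."""

    h: float = 1.0
    d: int = 1

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise InvalidParameterError("bandwidth h must be positive")
        if self.d < 1:
            raise InvalidParameterError("order d must be >= 1")


def gaussian_weights(X_train: np.ndarray, X_query: np.ndarray, h: float
                     ) -> np.ndarray:
    """(n_query, n_train) Gaussian kernel weights; weight 1 at zero distance."""
    d2 = ((X_query[:, None, :] - X_train[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2.0 * h * h))


def _truncated_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched symmetric pseudo-inverse solve: eigenvalues below
    ``PINV_RCOND`` times the largest are truncated (the weighted normal
    matrices are symmetric PSD, so eigh replaces the SVD of pinv)."""
    w, V = np.linalg.eigh(A)
    tol = PINV_RCOND * np.abs(w).max(axis=-1, keepdims=True)
    winv = np.where(w > tol, 1.0 / np.where(w > tol, w, 1.0), 0.0)
    return V @ (winv[..., None] * (V.transpose(0, 2, 1) @ b))


def _global_linear(X_train, Y_train, X_query):
    Phi = np.column_stack([np.ones(len(X_train)), X_train])
    coef, *_ = np.linalg.lstsq(Phi, Y_train, rcond=None)
    return np.column_stack([np.ones(len(X_query)), X_query]) @ coef


def local_linear_predict(X_train: np.ndarray, Y_train: np.ndarray,
                         X_query: np.ndarray, h: float) -> np.ndarray:
    """Order-1 local polynomial prediction at each query point.

    Solves, per query ``q``, the weighted least squares ``[c W] = (sum_m dy_m
    k_m phi_m') (sum_m phi_m k_m phi_m')^+`` with ``phi_m = [1; x_m - x_q]``
    and returns the local intercept ``c`` (the surface value at the query).
    Queries whose weights all underflow to zero fall back to the global
    linear fit (a warning is logged).

    Shapes: X_train (m, p), Y_train (m,) or (m, k), X_query (q, p); returns
    (q,) or (q, k).
    """
    if not h > 0:
        raise InvalidParameterError("bandwidth h must be positive")
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
    Y_train = np.asarray(Y_train, dtype=float)
    squeeze = Y_train.ndim == 1
    Y = Y_train[:, None] if squeeze else Y_train
    m, p = X_train.shape

    K = gaussian_weights(X_train, X_query, h)       # (q, m)
    # build per-query centered normal matrices from uncentered weighted
    # moments: with S0 = sum k, s1 = sum k x, S2 = sum k x x', the centered
    # blocks are s1c = s1 - S0 xq and S2c = S2 - s1 xq' - xq s1' + S0 xq xq'
    S0 = K.sum(axis=1)                              # (q,)
    s1 = K @ X_train                                # (q, p)
    KX = K[:, :, None] * X_train[None, :, :]        # (q, m, p)
    S2 = np.matmul(KX.transpose(0, 2, 1), X_train)  # (q, p, p)
    b0 = K @ Y                                      # (q, k)
    b1 = np.matmul(KX.transpose(0, 2, 1), Y)        # (q, p, k)

    # subnormal total mass gives garbage arithmetic: treat as no neighbours
    dead = S0 <= 1e-100
    xq = X_query
    s1c = s1 - S0[:, None] * xq
    cross = s1[:, :, None] * xq[:, None, :]
    S2c = (S2 - cross - cross.transpose(0, 2, 1)
           + S0[:, None, None] * xq[:, :, None] * xq[:, None, :])
    b1c = b1 - xq[:, :, None] * b0[:, None, :]

    A = np.empty((len(xq), p + 1, p + 1))
    A[:, 0, 0] = S0
    A[:, 0, 1:] = s1c
    A[:, 1:, 0] = s1c
    A[:, 1:, 1:] = S2c
    b = np.concatenate([b0[:, None, :], b1c], axis=1)  # (q, p+1, k)

    alive = ~dead
    out = np.empty((len(xq), Y.shape[1]))
    if np.any(alive):
        out[alive] = _truncated_solve(A[alive], b[alive])[:, 0, :]
    if np.any(dead):
        logger.warning(
            "%d query points had all-zero kernel weights (h=%g); "
            "falling back to the global linear fit", int(dead.sum()), h)
        out[dead] = np.atleast_2d(_global_linear(X_train, Y, X_query[dead]))
    return out[:, 0] if squeeze else out


def _lagged_queries(y: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stacked d-lag query vectors and first-difference targets.

    Returns (queries (rows, n*d), targets dy (rows, n), target times t)."""
    n, N = y.shape
    t = np.arange(d, N)
    Q = np.hstack([y[:, t - p].T for p in range(1, d + 1)])
    dy = (y[:, t] - y[:, t - 1]).T
    return Q, dy, t


def manifold_predict(train: Recording | list[Recording], test: Recording,
                     config: ManifoldConfig) -> PredictionSet:
    """One-step-ahead prediction of a test segment by local linear modelling.

    Query vectors stack ``d`` own-lags of all channels; the local model
    predicts the first difference ``y(t) - y(t-1)`` jointly over channels,
    so ``yhat(t|t-1) = y(t-1) + c``.
    """
    segs = [train] if isinstance(train, Recording) else list(train)
    d = config.d
    if sum(max(s.n_samples - d, 0) for s in segs) < d + 2:
        raise InsufficientSamplesError("not enough training samples for d lags")
    if test.n_samples <= d:
        raise InsufficientSamplesError("test segment shorter than d lags")
    t0 = time.perf_counter()
    parts = [_lagged_queries(s.values, d) for s in segs if s.n_samples > d]
    X_train = np.vstack([p[0] for p in parts])
    dY_train = np.vstack([p[1] for p in parts])
    X_test, _, t = _lagged_queries(test.values, d)
    delta = local_linear_predict(X_train, dY_train, X_test, config.h)
    pred = test.values[:, t - 1] + delta.T
    return PredictionSet.from_actual(test.values[:, t], pred, t,
                                     fit_time=0.0,  # model on demand
                                     predict_time=time.perf_counter() - t0)
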