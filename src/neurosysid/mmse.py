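"""MMSE (conditional-expectation) prediction by Gaussian-windowed histograms.

The minimum mean squared error predictor of a response given a conditioning
variable is the conditional expectation; it upper-bounds the accuracy of any
nonlinear predictor. It is estimated nonparametrically: training points near
the query (Gaussian window of standard deviation ``sigma = beta x training
range of the conditioning variable``) contribute their response values to an
``n_bins``-bin weighted histogram over the training response range; the
normalized histogram is a conditional distribution whose mean is the
prediction. Like the manifold predictor this is a model-on-demand method
with no training phase.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .datatypes import PredictionSet, Recording
from .errors import (DegenerateSignalError, InsufficientSamplesError,
                     InvalidParameterError)

__all__ = ["MMSEConfig", "mmse_conditional_mean", "mmse_predict"]

logger = logging.getLogger(__name__)


@dataclass
class MMSEConfig:
    """Window fraction ``beta``, histogram resolution, and conditioning mode.

    ``pairwise`` conditions each channel's first difference on a single
    channel's previous value (its own by default; ``pair_index`` maps target
    channel i -> conditioning channel j for cross pairs). ``scalar``
    conditions on the ``d`` own-lags with Euclidean distance.
    """

    beta: float = 0.02
    n_bins: int = 100
    mode: str = "pairwise"
    d: int = 1
    pair_index: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise InvalidParameterError("beta must be positive")
        if self.n_bins < 2:
            raise InvalidParameterError("n_bins must be >= 2")
        if self.mode not in ("pairwise", "scalar"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if self.d < 1:
            raise InvalidParameterError("order d must be >= 1")


def mmse_conditional_mean(cond_train: np.ndarray, resp_train: np.ndarray,
                          cond_query: np.ndarray, sigma: float,
                          n_bins: int = 100) -> np.ndarray:
    """Histogram-estimated E[response | conditioning = query].

    ``cond_train``/``cond_query`` may be 1-D (scalar conditioning) or 2-D
    ``(m, d)`` (Euclidean distance). The training response range is divided
    into ``n_bins`` equal bins; responses are quantized to bin centres, so
    the histogram mean equals the weighted mean of quantized responses.
    Queries whose window weights all vanish fall back to the unconditional
    (quantized) mean; a warning is logged.
    """
    if not sigma > 0:
        raise DegenerateSignalError(
            "window width sigma is zero: conditioning variable has no range")
    cond_train = np.asarray(cond_train, dtype=float)
    cond_query = np.asarray(cond_query, dtype=float)
    resp = np.asarray(resp_train, dtype=float)
    if cond_train.ndim == 1:
        d2 = (cond_query[:, None] - cond_train[None, :]) ** 2
    else:
        d2 = ((cond_query[:, None, :] - cond_train[None, :, :]) ** 2).sum(-1)
    W = np.exp(-d2 / (2.0 * sigma * sigma))

    lo, hi = resp.min(), resp.max()
    if hi > lo:
        width = (hi - lo) / n_bins
        idx = np.minimum(((resp - lo) / width).astype(int), n_bins - 1)
        resp_q = lo + (idx + 0.5) * width  # bin centres
    else:
        resp_q = resp  # point mass: all responses identical
    mass = W.sum(axis=1)
    dead = mass <= 0.0
    out = np.empty(len(cond_query))
    alive = ~dead
    out[alive] = (W[alive] @ resp_q) / mass[alive]
    if np.any(dead):
        logger.warning(
            "%d query points had zero histogram mass; falling back to the "
            "unconditional mean", int(dead.sum()))
        out[dead] = resp_q.mean()
    return out


def mmse_predict(train: Recording | list[Recording], test: Recording,
                 config: MMSEConfig) -> PredictionSet:
    """One-step-ahead MMSE prediction of a test segment.

    Pairwise mode estimates ``E[dy_i(t) | y_j(t-1)]`` with the window width
    set from the global training range (the per-pair scalar predictor);
    scalar mode estimates ``E[dy_i(t) | y_i(t-1), ..., y_i(t-d)]`` per
    channel with that channel's training range.
    """
    segs = [train] if isinstance(train, Recording) else list(train)
    d = config.d if config.mode == "scalar" else 1
    if test.n_samples <= d:
        raise InsufficientSamplesError("test segment shorter than d lags")
    if sum(max(s.n_samples - d, 0) for s in segs) < 2:
        raise InsufficientSamplesError("not enough training samples")
    t0 = time.perf_counter()
    n = test.n_channels
    t = np.arange(d, test.n_samples)
    pred = np.empty((n, t.size))

    if config.mode == "pairwise":
        global_range = (max(s.values.max() for s in segs)
                        - min(s.values.min() for s in segs))
        if global_range == 0:
            raise DegenerateSignalError("training data have zero range")
        sigma = config.beta * global_range
        pair = (list(range(n)) if config.pair_index is None
                else list(config.pair_index))
        for i in range(n):
            j = pair[i]
            cond_tr = np.concatenate([s.values[j, :-1] for s in segs])
            resp_tr = np.concatenate([np.diff(s.values[i]) for s in segs])
            delta = mmse_conditional_mean(cond_tr, resp_tr,
                                          test.values[j, t - 1], sigma,
                                          config.n_bins)
            pred[i] = test.values[i, t - 1] + delta
    else:
        for i in range(n):
            rng_i = (max(s.values[i].max() for s in segs)
                     - min(s.values[i].min() for s in segs))
            if rng_i == 0:
                raise DegenerateSignalError(
                    f"training channel {i} has zero range")
            sigma = config.beta * rng_i
            cond_parts, resp_parts = [], []
            for s in segs:
                if s.n_samples <= d:
                    continue
                tt = np.arange(d, s.n_samples)
                cond_parts.append(
                    np.column_stack([s.values[i, tt - p]
                                     for p in range(1, d + 1)]))
                resp_parts.append(s.values[i, tt] - s.values[i, tt - 1])
            cond_tr = np.vstack(cond_parts)
            resp_tr = np.concatenate(resp_parts)
            cond_q = np.column_stack([test.values[i, t - p]
                                      for p in range(1, d + 1)])
            delta = mmse_conditional_mean(cond_tr, resp_tr, cond_q, sigma,
                                          config.n_bins)
            pred[i] = test.values[i, t - 1] + delta

    return PredictionSet.from_actual(test.values[:, t], pred, t,
                                     fit_time=0.0,  # model on demand
                                     predict_time=time.perf_counter() - t0)
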