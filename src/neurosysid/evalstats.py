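"""Scoring (R^2, residual whiteness), cross-validation plans and model
comparison statistics.

R^2 is computed per channel against the constant predictor whose level is
the mean of the scored test samples; it is at most 1 and can be negative.
Residual whiteness uses the multivariate portmanteau Q statistic with a
randomization (time-shuffle) null: the test statistic is compared with the
95th percentile of Q over shuffled residuals, so ``Q / Q_thr <= 1`` means
whiteness is not rejected.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import PredictionSet, Recording
from .errors import (DegenerateSignalError, InsufficientSamplesError,
                     InvalidParameterError)

__all__ = [
    "ChannelR2", "WhitenessResult", "CVPlan", "ComparisonResult",
    "r2_per_channel", "portmanteau_q", "whiteness_test",
    "chi2_whiteness_univariate", "build_cv_plan", "signed_rank_compare",
    "evaluate_model", "default_whiteness_lags",
]

PINV_RCOND = 1e-10


@dataclass
class ChannelR2:
    """Per-channel R^2; entries are NaN where the test channel is constant."""

    r2: np.ndarray
    baseline_mean: np.ndarray
    n_samples: int

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.r2)

    @property
    def median(self) -> float:
        """Median over channels with a defined R^2."""
        vals = self.r2[self.defined]
        return float(np.median(vals)) if vals.size else float("nan")


@dataclass
class WhitenessResult:
    Q: float
    Q_thr: float
    M: int
    n_shuffles: int
    seed: int

    @property
    def ratio(self) -> float:
        return self.Q / self.Q_thr

    @property
    def rejected(self) -> bool:
        return self.ratio > 1.0


@dataclass
class CVPlan:
    """Folds of (training segments, test segment) plus a modality tag."""

    folds: list[tuple[list[Recording], Recording]]
    modality: str = "custom"

    def __len__(self) -> int:
        return len(self.folds)


@dataclass
class ComparisonResult:
    p_values: np.ndarray       # one-sided p[i, j]: method i > method j
    significant: np.ndarray    # BH-FDR mask at alpha
    direction: np.ndarray      # sign of the median paired difference
    alpha: float
    methods: list[str] = field(default_factory=list)


def r2_per_channel(actual: np.ndarray, predicted: np.ndarray) -> ChannelR2:
    """R^2_i = 1 - SSE_i / SST_i with the scored-test-sample mean baseline.

    Channels whose test samples are constant (zero SST) get a NaN sentinel.
    """
    actual = np.atleast_2d(np.asarray(actual, dtype=float))
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    if actual.shape != predicted.shape:
        raise InvalidParameterError("actual and predicted shapes differ")
    if actual.shape[1] < 2:
        raise InsufficientSamplesError("need >= 2 scored samples per channel")
    baseline = actual.mean(axis=1)
    sse = ((actual - predicted) ** 2).sum(axis=1)
    sst = ((actual - baseline[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, np.nan)
    return ChannelR2(r2, baseline, actual.shape[1])


def score_prediction_set(ps: PredictionSet) -> ChannelR2:
    scored = ps.scored
    return r2_per_channel(scored.actual(), scored.predictions)


# ---------------------------------------------------------------------------
# whiteness


def default_whiteness_lags(n_samples: int) -> int:
    return max(1, min(20, n_samples // 5))


def _cross_correlations(e: np.ndarray, M: int) -> list[np.ndarray]:
    n, N = e.shape
    return [(e[:, i:N - M + i] @ e[:, :N - M].T) / (N - M)
            for i in range(M + 1)]


def portmanteau_q(residuals: np.ndarray, M: int) -> float:
    """Multivariate portmanteau statistic
    ``Q = (N - M) sum_i tr(R(i)' R(0)^+ R(i) R(0)^+)`` with
    ``R(i) = (1/(N-M)) sum_t e(t+i) e(t)'`` and a tolerance-truncated
    pseudo-inverse of the lag-0 covariance."""
    e = np.atleast_2d(np.asarray(residuals, dtype=float))
    N = e.shape[1]
    if M < 1 or M >= N:
        raise InvalidParameterError("need 1 <= M < residual length")
    R = _cross_correlations(e, M)
    R0_inv = np.linalg.pinv(R[0], rcond=PINV_RCOND)
    q = 0.0
    for i in range(1, M + 1):
        q += np.trace(R[i].T @ R0_inv @ R[i] @ R0_inv)
    return float((N - M) * q)


def whiteness_test(residuals: np.ndarray, M: int | None = None,
                   n_shuffles: int = 100, seed: int = 0) -> WhitenessResult:
    """Portmanteau Q with a shuffle-based 95th-percentile threshold.

    The null distribution of Q is generated by permuting the time indices of
    the residuals ``n_shuffles`` times; deterministic given the seed.
    """
    e = np.atleast_2d(np.asarray(residuals, dtype=float))
    if M is None:
        M = default_whiteness_lags(e.shape[1])
    if n_shuffles < 20:
        import warnings
        warnings.warn("fewer than 20 shuffles: the 95th percentile of the "
                      "randomized null is unstable", stacklevel=2)
    q = portmanteau_q(e, M)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        null[k] = portmanteau_q(e[:, rng.permutation(e.shape[1])], M)
    return WhitenessResult(q, float(np.percentile(null, 95)), M, n_shuffles,
                           seed)


def chi2_whiteness_univariate(residual: np.ndarray, M: int,
                              ljung_box: bool = False
                              ) -> tuple[float, float]:
    """Box-Pierce (default) or Ljung-Box chi^2 whiteness test for a
    univariate residual; returns (statistic, p-value)."""
    e = np.asarray(residual, dtype=float).ravel()
    N = e.size
    if M >= N:
        raise InvalidParameterError("need M < residual length")
    if M == 0:
        return 0.0, 1.0
    e = e - e.mean()
    denom = float(e @ e)
    if denom == 0:
        raise DegenerateSignalError("constant residual has undefined "
                                    "autocorrelations")
    rho = np.array([float(e[i:] @ e[:N - i]) / denom for i in range(1, M + 1)])
    if ljung_box:
        stat = N * (N + 2) * float(np.sum(rho ** 2 / (N - np.arange(1, M + 1))))
    else:
        stat = N * float(np.sum(rho ** 2))
    return stat, float(stats.chi2.sf(stat, df=M))


# ---------------------------------------------------------------------------
# cross-validation plans


def build_cv_plan(recordings: Recording | list[Recording],
                  modality: str = "fmri-like",
                  reduce: str | None = None,
                  train_fraction: float = 0.8) -> CVPlan:
    """Build the modality's cross-validation folds.

    - ``fmri-like``: each recording is split into two halves; the resulting
      segments form a k-fold leave-one-segment-out plan (4 scans of 1200
      samples give 8 folds with 600-sample test segments).
      ``reduce='second_quarter'`` keeps only the second quarter of each
      segment (for pairwise methods: 600 -> 150 samples).
    - ``ieeg-like``: one fold per recording; the leading
      ``train_fraction`` (default 80%: the first 8 s of a 10 s segment)
      trains, the trailing remainder tests.
    - ``custom``: like ieeg-like with an explicit ``train_fraction``.
    """
    recs = [recordings] if isinstance(recordings, Recording) else list(recordings)
    if modality == "fmri-like":
        segments: list[Recording] = []
        for rec in recs:
            if rec.n_samples < 4:
                raise InsufficientSamplesError(
                    "recording too short to split into halves")
            half = rec.n_samples // 2
            for seg in (rec.slice_time(0, half), rec.slice_time(half, 2 * half)):
                if reduce == "second_quarter":
                    q = seg.n_samples // 4
                    seg = seg.slice_time(q, 2 * q)
                segments.append(seg)
        if len(segments) < 2:
            raise InsufficientSamplesError("need >= 2 segments for k-fold CV")
        folds = [([s for j, s in enumerate(segments) if j != k], segments[k])
                 for k in range(len(segments))]
        return CVPlan(folds, modality)
    if modality in ("ieeg-like", "custom"):
        if not (0 < train_fraction < 1):
            raise InvalidParameterError("train_fraction must lie in (0, 1)")
        folds = []
        for rec in recs:
            split = int(round(train_fraction * rec.n_samples))
            if split < 2 or rec.n_samples - split < 2:
                raise InsufficientSamplesError(
                    "recording too short for the train/test split")
            folds.append(([rec.slice_time(0, split)],
                          rec.slice_time(split, rec.n_samples)))
        return CVPlan(folds, modality)
    raise InvalidParameterError(f"unknown modality {modality!r}")


# ---------------------------------------------------------------------------
# model comparison


def signed_rank_compare(scores: np.ndarray, alpha: float = 0.05,
                        methods: list[str] | None = None) -> ComparisonResult:
    """One-sided Wilcoxon signed-rank tests between all ordered method pairs
    with Benjamini-Hochberg FDR control at ``alpha``.

    ``scores`` is (methods, samples); ``p[i, j]`` tests whether method i
    scores higher than method j. All-zero difference vectors give p = 1 by
    convention (Wilcoxon's zero-discard rule leaves nothing to rank).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    k, m = scores.shape
    if m < 5:
        raise InsufficientSamplesError("need >= 5 paired samples")
    p = np.full((k, k), np.nan)
    direction = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            diff = scores[i] - scores[j]
            direction[i, j] = np.sign(np.median(diff))
            if np.all(diff == 0):
                p[i, j] = 1.0
                continue
            res = stats.wilcoxon(scores[i], scores[j],
                                 alternative="greater", zero_method="wilcox")
            p[i, j] = float(res.pvalue)
    off = ~np.eye(k, dtype=bool)
    mask = np.zeros((k, k), dtype=bool)
    if k > 1:
        rejected, *_ = multipletests(p[off], alpha=alpha, method="fdr_bh")
        mask[off] = rejected
    return ComparisonResult(p, mask, direction, alpha,
                            methods or [f"m{i}" for i in range(k)])


# ---------------------------------------------------------------------------
# orchestration


def evaluate_model(family: str, params: dict, plan: CVPlan, seed: int = 0,
                   whiteness_lags: int | None = None,
                   n_shuffles: int = 100) -> pd.DataFrame:
    """Fit/predict one model family over every fold of a CV plan.

    Returns a flat table with one row per (fold, channel): R^2, the fold's
    whiteness Q and threshold, and fit/predict wall-times (training time is
    zero for the model-on-demand families and the zero model).
    """
    from . import linear, manifold, mlp, mmse, subspace  # local: avoid cycles

    rows = []
    for fold_id, (train, test) in enumerate(plan.folds):
        if family == "zero":
            ps = linear.predict_zero(test)
        elif family == "linear":
            model = linear.fit_ar(train, **params)
            ps = linear.predict_linear(model, test)
        elif family == "subspace":
            model = subspace.fit_subspace(train, **params)
            ps = subspace.predict_subspace(model, test)
        elif family == "manifold":
            ps = manifold.manifold_predict(train, test,
                                           manifold.ManifoldConfig(**params))
        elif family == "mmse":
            ps = mmse.mmse_predict(train, test, mmse.MMSEConfig(**params))
        elif family == "mlp":
            net = mlp.fit_mlp(train, mlp.MLPConfig(**params), seed=seed)
            ps = mlp.predict_mlp(net, test)
        else:
            raise InvalidParameterError(f"unknown model family {family!r}")
        scored = ps.scored
        r2 = r2_per_channel(scored.actual(), scored.predictions)
        wt = whiteness_test(scored.residuals, M=whiteness_lags,
                            n_shuffles=n_shuffles, seed=seed + fold_id)
        for ch in range(test.n_channels):
            rows.append({
                "fold": fold_id, "channel": test.labels[ch], "family": family,
                "r2": r2.r2[ch], "Q": wt.Q, "Q_thr": wt.Q_thr,
                "fit_time": ps.fit_time, "predict_time": ps.predict_time,
                "seed": seed,
            })
    return pd.DataFrame(rows)
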