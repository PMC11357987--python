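"""Linearizing-mechanism experiments: spatial averaging, spatial correlation,
temporal averaging, observation noise, and sample-limited dimensionality.

Each experiment sweeps one mechanism parameter and reports the
cross-validated R^2 of a linear predictor and of the optimal nonlinear
predictor (the Gaussian-window MMSE estimator for scalar relations, the
locally linear manifold predictor for high-dimensional ones) on identical
data within each repetition (paired-seed design). The nonlinear-minus-linear
R^2 gap quantifies how much nonlinearity remains detectable; a mechanism
"linearizes" once the gap falls below a small epsilon (default 0.01).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import Recording
from .errors import InvalidParameterError
from .linear import fit_ar, predict_linear
from .manifold import local_linear_predict
from .mmse import MMSEConfig, mmse_conditional_mean, mmse_predict
from .synthgen import (IzhikevichParams, NoiseSpec, add_noise_at_snr,
                       gaussian_lpf, gen_colored_signal, gen_iid_tanh_ensemble,
                       gen_sphere_correlated_ensemble, gen_sum_tanh_dataset,
                       simulate_izhikevich)

__all__ = [
    "EffectCurve", "spatial_averaging_curve", "sphere_averaging_curve",
    "temporal_averaging_curve", "snr_curve", "dimensionality_curve",
    "izhikevich_averaging", "gap_threshold",
    "DEFAULT_N_AVE_GRID", "DEFAULT_SNR_GRID", "DEFAULT_F_CUTOFF_GRID",
    "DEFAULT_P_GRID", "DEFAULT_N_DIM_GRID", "DEFAULT_H_GRID",
]

DEFAULT_N_AVE_GRID = (1, 2, 3, 5, 8, 10, 20)
DEFAULT_SNR_GRID = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 100.0)
DEFAULT_F_CUTOFF_GRID = (1.0, 0.5, 0.2, 0.1, 0.05, 0.02)
DEFAULT_P_GRID = (0.0, 1.0, 2.0, 3.0)
DEFAULT_N_DIM_GRID = (1, 5, 10, 20, 40)
DEFAULT_H_GRID = tuple(np.geomspace(0.1, 10.0, 7))


@dataclass
class EffectCurve:
    """Linear vs nonlinear cross-validated R^2 along a mechanism grid."""

    grid: np.ndarray
    r2_linear: np.ndarray          # mean over repetitions, per grid point
    r2_nonlinear: np.ndarray
    r2_linear_sem: np.ndarray
    r2_nonlinear_sem: np.ndarray
    gap: np.ndarray                # per-rep gaps, shape (grid, reps)
    optimal_h: np.ndarray | None = None
    reps: int = 1
    seeds: list[int] = field(default_factory=list)
    label: str = ""

    @property
    def gap_mean(self) -> np.ndarray:
        return self.gap.mean(axis=1)

    @property
    def gap_sem(self) -> np.ndarray:
        return self.gap.std(axis=1, ddof=1) / np.sqrt(self.gap.shape[1]) \
            if self.gap.shape[1] > 1 else np.zeros(self.gap.shape[0])

    def to_dict(self) -> dict:
        out = {"grid": self.grid.tolist(),
               "r2_linear": self.r2_linear.tolist(),
               "r2_nonlinear": self.r2_nonlinear.tolist(),
               "r2_linear_sem": self.r2_linear_sem.tolist(),
               "r2_nonlinear_sem": self.r2_nonlinear_sem.tolist(),
               "gap_mean": self.gap_mean.tolist(),
               "gap_sem": self.gap_sem.tolist(),
               "reps": self.reps, "seeds": self.seeds, "label": self.label}
        if self.optimal_h is not None:
            out["optimal_h"] = self.optimal_h.tolist()
        return out


def _rep_seeds(seed: int, reps: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=reps)]


def _contiguous_folds(n: int, k: int):
    edges = np.linspace(0, n, k + 1).astype(int)
    for i in range(k):
        test = np.arange(edges[i], edges[i + 1])
        train = np.concatenate([np.arange(0, edges[i]),
                                np.arange(edges[i + 1], n)])
        yield train, test


def _r2(actual: np.ndarray, predicted: np.ndarray) -> float:
    sst = float(((actual - actual.mean()) ** 2).sum())
    if sst == 0:
        return float("nan")
    return 1.0 - float(((actual - predicted) ** 2).sum()) / sst


def _static_cv_r2(x: np.ndarray, y: np.ndarray, beta: float, n_bins: int,
                  n_folds: int = 2) -> tuple[float, float]:
    """Mean k-fold CV R^2 of (OLS linear regression, MMSE) predicting y
    from x; the MMSE window is beta times the training range of x."""
    lin, non = [], []
    for tr, te in _contiguous_folds(x.size, n_folds):
        slope, intercept = np.polyfit(x[tr], y[tr], 1)
        lin.append(_r2(y[te], slope * x[te] + intercept))
        sigma = beta * (x[tr].max() - x[tr].min())
        non.append(_r2(y[te], mmse_conditional_mean(x[tr], y[tr], x[te],
                                                    sigma, n_bins)))
    return float(np.mean(lin)), float(np.mean(non))


def _assemble(grid, lin, non, opt_h=None, reps=1, seeds=(), label=""):
    lin = np.asarray(lin)   # (grid, reps)
    non = np.asarray(non)
    sem = (lambda a: a.std(axis=1, ddof=1) / np.sqrt(a.shape[1])
           if a.shape[1] > 1 else np.zeros(a.shape[0]))
    return EffectCurve(np.asarray(grid, dtype=float), lin.mean(axis=1),
                       non.mean(axis=1), sem(lin), sem(non), non - lin,
                       None if opt_h is None else np.asarray(opt_h).mean(axis=1),
                       reps, list(seeds), label)


# ---------------------------------------------------------------------------


def spatial_averaging_curve(n_ave_grid=DEFAULT_N_AVE_GRID[:6], T: int = 2000,
                            reps: int = 20, seed: int = 0, beta: float = 0.02,
                            n_bins: int = 100) -> EffectCurve:
    """Average N_ave iid (x, tanh(x)) pairs and score <x> -> <y> prediction."""
    if len(n_ave_grid) == 0:
        raise InvalidParameterError("grid must be nonempty")
    seeds = _rep_seeds(seed, reps)
    lin = np.empty((len(n_ave_grid), reps))
    non = np.empty_like(lin)
    for gi, n_ave in enumerate(n_ave_grid):
        for ri, s in enumerate(seeds):
            xe, ye = gen_iid_tanh_ensemble(int(n_ave), T, s)
            lin[gi, ri], non[gi, ri] = _static_cv_r2(
                xe.average, ye.average, beta, n_bins)
    return _assemble(n_ave_grid, lin, non, reps=reps, seeds=seeds,
                     label="spatial_averaging")


def sphere_averaging_curve(corr_length_grid=(0.1, 1.0, np.inf),
                           n_ave_grid=(1, 5, 20), T: int = 2000,
                           reps: int = 10, seed: int = 0, beta: float = 0.02,
                           n_bins: int = 100) -> dict[float, EffectCurve]:
    """Spatially correlated units on the unit ball: one curve per
    correlation length, swept over N_ave."""
    seeds = _rep_seeds(seed, reps)
    out: dict[float, EffectCurve] = {}
    for cl in corr_length_grid:
        lin = np.empty((len(n_ave_grid), reps))
        non = np.empty_like(lin)
        for gi, n_ave in enumerate(n_ave_grid):
            for ri, s in enumerate(seeds):
                xe, ye, _ = gen_sphere_correlated_ensemble(int(n_ave), cl, T, s)
                lin[gi, ri], non[gi, ri] = _static_cv_r2(
                    xe.average, ye.average, beta, n_bins)
        out[float(cl)] = _assemble(n_ave_grid, lin, non, reps=reps,
                                   seeds=seeds,
                                   label=f"sphere_corr_length={cl}")
    return out


def temporal_averaging_curve(f_cutoff_grid=DEFAULT_F_CUTOFF_GRID,
                             p_grid=DEFAULT_P_GRID, T: int = 2000,
                             reps: int = 10, seed: int = 0,
                             beta: float = 0.02, n_bins: int = 100
                             ) -> dict[float, EffectCurve]:
    """Gaussian low-pass filtering of colored (x, tanh(x)) pairs: one curve
    per PSD decay rate p, swept over the cutoff frequency."""
    seeds = _rep_seeds(seed, reps)
    out: dict[float, EffectCurve] = {}
    for p in p_grid:
        lin = np.empty((len(f_cutoff_grid), reps))
        non = np.empty_like(lin)
        for gi, fc in enumerate(f_cutoff_grid):
            for ri, s in enumerate(seeds):
                x = gen_colored_signal(T, float(p), s).values[0]
                y = np.tanh(x)
                xf = gaussian_lpf(x, float(fc))
                yf = gaussian_lpf(y, float(fc))
                lin[gi, ri], non[gi, ri] = _static_cv_r2(xf, yf, beta, n_bins)
        out[float(p)] = _assemble(f_cutoff_grid, lin, non, reps=reps,
                                  seeds=seeds, label=f"temporal_p={p}")
    return out


def snr_curve(snr_grid=DEFAULT_SNR_GRID[:6], T: int = 2000, reps: int = 20,
              seed: int = 0, n_bins: int = 100) -> EffectCurve:
    """Independent observation noise on x and tanh(x) at each grid SNR.

    The MMSE window follows the noise level: beta = 0.02 + 0.02 / SNR."""
    seeds = _rep_seeds(seed, reps)
    lin = np.empty((len(snr_grid), reps))
    non = np.empty_like(lin)
    for gi, snr in enumerate(snr_grid):
        beta = 0.02 + 0.02 / float(snr)
        for ri, s in enumerate(seeds):
            rng = np.random.default_rng(s)
            x = rng.standard_normal(T)
            y = np.tanh(x)
            sub = rng.integers(0, 2**31 - 1, 2)
            xn = add_noise_at_snr(x, NoiseSpec(float(snr)), int(sub[0]))
            yn = add_noise_at_snr(y, NoiseSpec(float(snr)), int(sub[1]))
            lin[gi, ri], non[gi, ri] = _static_cv_r2(xn, yn, beta, n_bins)
    return _assemble(snr_grid, lin, non, reps=reps, seeds=seeds, label="snr")


def dimensionality_curve(n_grid=DEFAULT_N_DIM_GRID[1:], N: int = 1000,
                         h_grid=DEFAULT_H_GRID, iters: int = 10,
                         seed: int = 0, n_folds: int = 5,
                         margin: float = 0.005) -> EffectCurve:
    """y = tanh(x_1 + ... + x_n) with N samples: OLS vs the locally linear
    manifold predictor with the per-fold best bandwidth from ``h_grid``."""
    import logging
    seeds = _rep_seeds(seed, iters)
    lin = np.empty((len(n_grid), iters))
    non = np.empty_like(lin)
    opt_h = np.empty_like(lin)
    h_grid = np.asarray(h_grid, dtype=float)
    # tiny-h grid points legitimately have empty neighbourhoods in high
    # dimension; the per-query fallback warnings are expected here
    manifold_logger = logging.getLogger("neurosysid.manifold")
    old_level = manifold_logger.level
    manifold_logger.setLevel(logging.ERROR)
    for gi, n in enumerate(n_grid):
        for ri, s in enumerate(seeds):
            X, y = gen_sum_tanh_dataset(int(n), N, s)
            lin_folds, non_folds, h_folds = [], [], []
            for tr, te in _contiguous_folds(N, n_folds):
                Phi_tr = np.column_stack([np.ones(tr.size), X[tr]])
                Phi_te = np.column_stack([np.ones(te.size), X[te]])
                coef, *_ = np.linalg.lstsq(Phi_tr, y[tr], rcond=None)
                lin_folds.append(_r2(y[te], Phi_te @ coef))
                r2_by_h = [_r2(y[te], local_linear_predict(X[tr], y[tr],
                                                           X[te], h))
                           for h in h_grid]
                best = int(np.argmax(r2_by_h))
                non_folds.append(r2_by_h[best])
                h_folds.append(h_grid[best])
            lin[gi, ri] = np.mean(lin_folds)
            non[gi, ri] = np.mean(non_folds)
            opt_h[gi, ri] = np.mean(h_folds)
    manifold_logger.setLevel(old_level)
    return _assemble(n_grid, lin, non, opt_h=opt_h, reps=iters, seeds=seeds,
                     label="dimensionality")


def izhikevich_averaging(n_ave_grid=(1, 10, 100, 1000),
                         params: IzhikevichParams | None = None,
                         duration_ms: float = 3000.0, bin_ms: float = 1.0,
                         reps: int = 10, seed: int = 0, beta: float = 0.02,
                         n_bins: int = 100) -> EffectCurve:
    """Population-average membrane potential of uncoupled noisy neurons:
    scalar AR-1 linear prediction vs the scalar MMSE predictor on the
    neuron-averaged, time-binned series."""
    if params is None:
        params = IzhikevichParams(input_noise_std=5.0)
    seeds = _rep_seeds(seed, reps)
    bin_steps = max(1, int(round(bin_ms / params.dt)))
    lin = np.empty((len(n_ave_grid), reps))
    non = np.empty_like(lin)
    for gi, n_ave in enumerate(n_ave_grid):
        for ri, s in enumerate(seeds):
            V, _ = simulate_izhikevich(params, int(n_ave), duration_ms, s)
            avg = V.mean(axis=0)
            usable = (avg.size // bin_steps) * bin_steps
            series = avg[:usable].reshape(-1, bin_steps).mean(axis=1)
            half = series.size // 2
            r2l, r2n = [], []
            for train_sl, test_sl in ((slice(0, half), slice(half, None)),
                                      (slice(half, None), slice(0, half))):
                train = Recording(series[None, train_sl], bin_ms / 1000.0)
                test = Recording(series[None, test_sl], bin_ms / 1000.0)
                model = fit_ar(train, d=1, structure="scalar")
                psl = predict_linear(model, test)
                psn = mmse_predict(train, test,
                                   MMSEConfig(beta=beta, n_bins=n_bins,
                                              mode="scalar", d=1))
                r2l.append(_r2(psl.actual()[0], psl.predictions[0]))
                r2n.append(_r2(psn.actual()[0], psn.predictions[0]))
            lin[gi, ri] = np.mean(r2l)
            non[gi, ri] = np.mean(r2n)
    return _assemble(n_ave_grid, lin, non, reps=reps, seeds=seeds,
                     label="izhikevich_averaging")


def gap_threshold(curve: EffectCurve, epsilon: float = 0.01,
                  direction: str = "smallest") -> float | None:
    """The smallest (or largest) grid value whose mean nonlinear-minus-linear
    gap is below ``epsilon``; None if no grid point qualifies."""
    if not epsilon > 0:
        raise InvalidParameterError("epsilon must be positive")
    if curve.grid.size == 0:
        raise InvalidParameterError("curve is empty")
    below = curve.gap_mean < epsilon
    if not np.any(below):
        return None
    order = np.argsort(curve.grid)
    hits = [curve.grid[i] for i in order if below[i]]
    return float(hits[0] if direction == "smallest" else hits[-1])
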