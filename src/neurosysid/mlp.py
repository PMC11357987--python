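"""Feedforward ReLU network predicting first differences from stacked lags.

The network maps ``(y(t-1), ..., y(t-d))`` to ``y(t) - y(t-1)`` through ``D``
blocks of [fully connected -> batch normalization -> ReLU -> 50% dropout]
and a final fully connected layer. Training is minibatch Adam on mean
squared error with a fixed seed, a 10% validation split for early stopping
and a 200-epoch cap; evaluation runs with dropout disabled and batch-norm
running statistics. Inputs are standardized and targets scaled by their
standard deviation only (no shift), so a network with a zeroed output layer
predicts a zero first difference — exactly the zero-order-hold baseline.

Implemented directly on numpy: the architecture (batch norm, dropout, a
zeroable output layer, identity-activation ablation) is part of the model
contract and is not expressible through a generic off-the-shelf regressor.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .datatypes import PredictionSet, Recording
from .errors import (InsufficientSamplesError, InvalidParameterError,
                     TrainingFailureError)

__all__ = ["MLPConfig", "MLPNetwork", "fit_mlp", "predict_mlp"]

_EPS = 1e-5


@dataclass
class MLPConfig:
    depth: int = 2           # number of FC->BN->ReLU->dropout blocks
    width: int = 10          # units per block
    d: int = 1               # autoregressive lags in the input
    dropout: float = 0.5
    batchnorm: bool = True
    activation: str = "relu"  # 'identity' ablates the nonlinearity
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-2
    val_fraction: float = 0.1
    patience: int = 20

    def __post_init__(self) -> None:
        if self.depth < 1 or self.width < 1:
            raise InvalidParameterError("depth and width must be >= 1")
        if self.d < 1:
            raise InvalidParameterError("order d must be >= 1")
        if not (0 <= self.dropout < 1):
            raise InvalidParameterError("dropout must lie in [0, 1)")
        if self.activation not in ("relu", "identity"):
            raise InvalidParameterError(f"unknown activation {self.activation!r}")


class MLPNetwork:
    """Weights, batch-norm state and preprocessing scalers of a fitted net."""

    def __init__(self, config: MLPConfig, n_in: int, n_out: int, rng):
        self.config = config
        self.n_in, self.n_out = n_in, n_out
        dims = [n_in] + [config.width] * config.depth
        # uniform fan-in init for weights AND biases spreads the ReLU
        # breakpoints away from the origin at initialization
        self.W = [rng.uniform(-1, 1, (dims[i], dims[i + 1]))
                  / np.sqrt(dims[i]) for i in range(config.depth)]
        self.b = [rng.uniform(-1, 1, config.width) / np.sqrt(dims[i])
                  for i in range(config.depth)]
        self.gamma = [np.ones(config.width) for _ in range(config.depth)]
        self.beta = [np.zeros(config.width) for _ in range(config.depth)]
        self.run_mean = [np.zeros(config.width) for _ in range(config.depth)]
        self.run_var = [np.ones(config.width) for _ in range(config.depth)]
        self.W_out = rng.standard_normal((dims[-1], n_out)) * np.sqrt(1.0 / dims[-1])
        self.b_out = np.zeros(n_out)
        # preprocessing: input standardization, output scale (no shift)
        self.x_mean = np.zeros(n_in)
        self.x_std = np.ones(n_in)
        self.y_scale = np.ones(n_out)
        self.train_mean: np.ndarray | None = None
        self.fit_time = 0.0

    # -- forward / backward ------------------------------------------------

    def _params(self):
        return (self.W + self.b + self.gamma + self.beta
                + [self.W_out, self.b_out])

    def forward(self, X: np.ndarray, training: bool = False, rng=None):
        cfg = self.config
        cache = []
        a = X
        for k in range(cfg.depth):
            z = a @ self.W[k] + self.b[k]
            if cfg.batchnorm:
                if training:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    self.run_mean[k] = 0.9 * self.run_mean[k] + 0.1 * mu
                    self.run_var[k] = 0.9 * self.run_var[k] + 0.1 * var
                else:
                    mu, var = self.run_mean[k], self.run_var[k]
                inv_std = 1.0 / np.sqrt(var + _EPS)
                zhat = (z - mu) * inv_std
                h = self.gamma[k] * zhat + self.beta[k]
            else:
                zhat, inv_std, h = z, None, z
            pre = h
            act = np.maximum(h, 0.0) if cfg.activation == "relu" else h
            if training and cfg.dropout > 0:
                mask = (rng.uniform(size=act.shape) >= cfg.dropout)
                act = act * mask / (1.0 - cfg.dropout)
            else:
                mask = None
            cache.append((a, zhat, inv_std, pre, mask))
            a = act
        out = a @ self.W_out + self.b_out
        cache.append(a)
        return out, cache

    def backward(self, dout: np.ndarray, cache):
        cfg = self.config
        grads_W = [None] * cfg.depth
        grads_b = [None] * cfg.depth
        grads_g = [None] * cfg.depth
        grads_be = [None] * cfg.depth
        a_last = cache[-1]
        gW_out = a_last.T @ dout
        gb_out = dout.sum(axis=0)
        da = dout @ self.W_out.T
        for k in reversed(range(cfg.depth)):
            a_in, zhat, inv_std, pre, mask = cache[k]
            if mask is not None:
                da = da * mask / (1.0 - cfg.dropout)
            if cfg.activation == "relu":
                da = da * (pre > 0)
            if cfg.batchnorm:
                m = da.shape[0]
                grads_g[k] = (da * zhat).sum(axis=0)
                grads_be[k] = da.sum(axis=0)
                dz = (self.gamma[k] * inv_std / m) * (
                    m * da - da.sum(axis=0) - zhat * (da * zhat).sum(axis=0))
            else:
                grads_g[k] = np.zeros_like(self.gamma[k])
                grads_be[k] = np.zeros_like(self.beta[k])
                dz = da
            grads_W[k] = a_in.T @ dz
            grads_b[k] = dz.sum(axis=0)
            da = dz @ self.W[k].T
        return grads_W + grads_b + grads_g + grads_be + [gW_out, gb_out]

    # -- inference ---------------------------------------------------------

    def predict_delta(self, X_raw: np.ndarray) -> np.ndarray:
        """First-difference predictions on raw (unstandardized) inputs."""
        X = (X_raw - self.x_mean) / self.x_std
        out, _ = self.forward(X, training=False)
        return out * self.y_scale

    def zero_output_layer(self) -> None:
        """Force the final layer to zero: the net becomes the zero model."""
        self.W_out[:] = 0.0
        self.b_out[:] = 0.0


def _lagged_dataset(segments: list[Recording], d: int):
    X_parts, Y_parts = [], []
    for s in segments:
        y = s.values
        if y.shape[1] <= d:
            continue
        t = np.arange(d, y.shape[1])
        X_parts.append(np.hstack([y[:, t - p].T for p in range(1, d + 1)]))
        Y_parts.append((y[:, t] - y[:, t - 1]).T)
    if not X_parts:
        raise InsufficientSamplesError("no training segment longer than d lags")
    return np.vstack(X_parts), np.vstack(Y_parts)


def fit_mlp(train: Recording | list[Recording], config: MLPConfig,
            seed: int = 0) -> MLPNetwork:
    """Train the NARX network on stacked lags -> first differences."""
    segs = [train] if isinstance(train, Recording) else list(train)
    X, Y = _lagged_dataset(segs, config.d)
    if X.shape[0] <= config.batch_size:
        raise InsufficientSamplesError(
            "training needs more samples than one batch")
    t0 = time.perf_counter()
    rng = np.random.default_rng(seed)
    net = MLPNetwork(config, X.shape[1], Y.shape[1], rng)
    net.x_mean = X.mean(axis=0)
    net.x_std = X.std(axis=0)
    net.x_std[net.x_std == 0] = 1.0
    net.y_scale = Y.std(axis=0)
    net.y_scale[net.y_scale == 0] = 1.0
    Xs = (X - net.x_mean) / net.x_std
    Ys = Y / net.y_scale

    perm = rng.permutation(X.shape[0])
    n_val = max(1, int(round(config.val_fraction * X.shape[0])))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    X_tr, Y_tr = Xs[tr_idx], Ys[tr_idx]
    X_val, Y_val = Xs[val_idx], Ys[val_idx]

    params = net._params()
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    step = 0
    best_val = np.inf
    best_snapshot = None
    since_best = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    for _epoch in range(config.epochs):
        # cosine annealing: large early steps explore, small late steps
        # settle the dropout-noise-averaged optimum
        lr_epoch = config.learning_rate * 0.5 * (
            1.0 + np.cos(np.pi * _epoch / config.epochs))
        order = rng.permutation(len(X_tr))
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            if batch.size < 2:
                continue
            out, cache = net.forward(X_tr[batch], training=True, rng=rng)
            err = out - Y_tr[batch]
            loss = float((err ** 2).mean())
            if not np.isfinite(loss):
                raise TrainingFailureError("non-finite training loss")
            dout = 2.0 * err / err.size
            grads = net.backward(dout, cache)
            step += 1
            lr_t = lr_epoch * (np.sqrt(1 - beta2 ** step)
                               / (1 - beta1 ** step))
            for p, g, mo, ve in zip(params, grads, m_state, v_state):
                mo *= beta1
                mo += (1 - beta1) * g
                ve *= beta2
                ve += (1 - beta2) * g * g
                p -= lr_t * mo / (np.sqrt(ve) + eps)
        _recalibrate_batchnorm(net, X_tr)  # stable stats for the val check
        val_out, _ = net.forward(X_val, training=False)
        val_loss = float(((val_out - Y_val) ** 2).mean())
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_snapshot = ([p.copy() for p in params],
                             [m.copy() for m in net.run_mean],
                             [v.copy() for v in net.run_var])
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_snapshot is not None:
        snap_params, snap_mean, snap_var = best_snapshot
        for p, snap in zip(params, snap_params):
            p[:] = snap
        net.run_mean = [m.copy() for m in snap_mean]
        net.run_var = [v.copy() for v in snap_var]
    _recalibrate_batchnorm(net, X_tr)
    net.fit_time = time.perf_counter() - t0
    return net


def _recalibrate_batchnorm(net: MLPNetwork, X: np.ndarray) -> None:
    """Replace batch-norm running statistics with exact full-training-set
    statistics (dropout off), so evaluation matches the fitted function."""
    cfg = net.config
    if not cfg.batchnorm:
        return
    a = X
    for k in range(cfg.depth):
        z = a @ net.W[k] + net.b[k]
        net.run_mean[k] = z.mean(axis=0)
        net.run_var[k] = z.var(axis=0)
        zhat = (z - net.run_mean[k]) / np.sqrt(net.run_var[k] + _EPS)
        h = net.gamma[k] * zhat + net.beta[k]
        a = np.maximum(h, 0.0) if cfg.activation == "relu" else h


def predict_mlp(net: MLPNetwork, test: Recording) -> PredictionSet:
    """One-step-ahead predictions: ``yhat(t|t-1) = y(t-1) + f(lags)``."""
    d = net.config.d
    if test.n_samples <= d:
        raise InsufficientSamplesError("test segment shorter than d lags")
    t0 = time.perf_counter()
    y = test.values
    t = np.arange(d, y.shape[1])
    X = np.hstack([y[:, t - p].T for p in range(1, d + 1)])
    delta = net.predict_delta(X)
    pred = y[:, t - 1] + delta.T
    return PredictionSet.from_actual(y[:, t], pred, t, fit_time=net.fit_time,
                                     predict_time=time.perf_counter() - t0)
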