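# neurosysid

Cross-validated prediction-error benchmarking of linear versus nonlinear
models for multivariate neural time series, together with a synthetic-data
suite for studying why macroscopic neural recordings (resting-state fMRI,
intracranial EEG) so often look linear.

## The problem

Given a channels × time recording **y**(t), system identification asks which
family of one-step-ahead predictors ŷ(t|t−1) best explains the dynamics.
All model families here are fit and scored under a single contract built on
the one-step prediction error

    ε(t) = y(t) − ŷ(t|t−1)

with two cross-validated figures of merit per channel i:

* accuracy,  R²ᵢ = 1 − Σₜ εᵢ(t)² / Σₜ (yᵢ(t) − ȳᵢ)²  (≤ 1, can be negative;
  0 means "no better than the constant predictor"), and
* residual whiteness, via the multivariate portmanteau statistic
  Q = (N−M) Σᵢ₌₁..M tr(R̂(i)ᵀ R̂(0)⁺ R̂(i) R̂(0)⁺) compared against a
  randomization threshold Q_thr (the 95th percentile of Q over
  time-shuffled residuals); Q/Q_thr ≤ 1 means whiteness is not rejected.

Model families (module → contract `fit`/`predict` on `Recording` objects):

| family     | model |
|------------|-------|
| `zero`     | zero-order hold ŷ(t|t−1) = y(t−1) (the baseline any model must beat) |
| `linear`   | first-difference (V)AR: y(t) − y(t−1) = W y(t−1) + Σₚ Dₚ y(t−p) + e(t); dense, LASSO-sparse, or scalar (decoupled) structure; W is the effective-connectivity matrix |
| `subspace` | innovation-form state space learned by covariance-based stochastic subspace identification with a Riccati steady-state Kalman predictor gain |
| `manifold` | locally linear (model-on-demand) order-1 local polynomial with Gaussian kernel bandwidth h; h → ∞ recovers a global linear model |
| `mmse`     | conditional-expectation (MMSE) predictor E[Δy | conditioning] estimated by Gaussian-window weighted histograms — the upper bound on any nonlinear predictor |
| `mlp`      | feedforward ReLU network on stacked lags predicting first differences (fully connected → batch norm → ReLU → 50% dropout blocks) |

The `effects` module reproduces the four linearizing mechanisms on data with
known ground truth: spatial averaging of N_ave sigmoidal units, spatial
correlation decaying with distance on the unit ball, temporal averaging
(Gaussian low-pass filtering of 1/f^p signals), independent observation
noise at a prescribed SNR, and sample-limited dimensionality
(y = tanh(x₁+…+xₙ) from N = 1000 samples). Each experiment reports the
cross-validated R² of a linear and of the optimal nonlinear predictor on
identical data; their gap quantifies detectable nonlinearity. An Izhikevich
spiking-neuron simulator (Euler, 0.1 ms) provides a population whose ground
truth is strongly nonlinear.

## Worked example

```python
import numpy as np
import neurosysid as ns
from neurosysid.synthgen import gen_stable_var
from neurosysid import effects as fx

# 5-channel stable sparse VAR with known effective connectivity
rec, truth = gen_stable_var(n=5, d=1, T=4000, seed=42)
train, test = rec.slice_time(0, 3000), rec.slice_time(3000, 4000)

model = ns.fit_ar(train, d=1)                      # dense least squares
ps = ns.predict_linear(model, test)                # one-step-ahead
r2 = ns.r2_per_channel(ps.actual(), ps.predictions)
wt = ns.whiteness_test(ps.residuals, seed=0)
print(f"max |W_hat - W|   : {np.abs(model.W - truth.W).max():.4f}")
print(f"median held-out R2: {r2.median:.4f}")
print(f"whiteness Q/Q_thr : {wt.ratio:.3f}  (white: {not wt.rejected})")

curve = fx.spatial_averaging_curve(n_ave_grid=(1, 5, 10), T=2000,
                                   reps=10, seed=0)
for n, g in zip(curve.grid, curve.gap_mean):
    print(f"N_ave={int(n):2d}  MMSE-minus-linear R2 gap = {g:+.4f}")
print("linearized at N_ave =", fx.gap_threshold(curve, 0.01))
```

prints

```
max |W_hat - W|   : 0.0262
median held-out R2: 0.6335
whiteness Q/Q_thr : 0.845  (white: True)
N_ave= 1  MMSE-minus-linear R2 gap = +0.0699
N_ave= 5  MMSE-minus-linear R2 gap = +0.0004
N_ave=10  MMSE-minus-linear R2 gap = -0.0012
linearized at N_ave = 5.0
```

The fitted drift matrix recovers the ground truth to 0.03, the held-out R²
is far above the zero model, and the residuals pass the whiteness test — the
linear model has captured all temporal structure it was given. The
spatial-averaging sweep shows the core phenomenon: a single (x, tanh(x))
pair leaves a clear nonlinear advantage (gap ≈ 0.07), which vanishes once
about five independent pairs are averaged.

## Command line

```sh
neurosysid simulate rec.csv --kind var --n 5 --t 2000 --seed 0
neurosysid benchmark run.yaml report.json --families zero,linear,mmse
neurosysid effects spatial curve.json --reps 20 --seed 1
neurosysid tune run.yaml traj.json --param d:integer:1:1:10
```

Every subcommand reads a YAML `RunConfig`, seeds all randomness from one
root seed, and writes a JSON report with full provenance.

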