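# Methods

This note documents the models, estimators and simulation recipes
implemented in `neurosysid`, the defaults they use, and the design choices
made where several reasonable constructions exist.

## Prediction-error contract

All predictors consume a `Recording` (channels × time, fixed sampling
interval) and emit a `PredictionSet` of one-step-ahead predictions
ŷ(t|t−1) with residuals ε(t) = y(t) − ŷ(t|t−1) aligned to test-time
indices. Within each test segment, predictions start at t = d+1 (d = model
order); lags never cross segment boundaries, because segments represent
independent recordings. Causality is a tested invariant: perturbing y(t)
never changes ŷ(s|s−1) for s ≤ t.

R² is computed per channel against the constant predictor whose level is
the mean of the *scored test samples*. Defining the baseline on the test
segment (rather than the training mean) makes "R² = 0 ⇔ as good as the
constant predictor" literally true on the scored data. Channels whose test
segment is constant have an undefined R² and carry a NaN sentinel; they are
excluded from medians and counted in reports.

## Model families

**Zero model.** ŷ(t|t−1) = y(t−1). Not a model of anything — the floor any
real model must beat, and stronger than the constant predictor whenever the
series has temporal persistence.

**Linear (V)AR on first differences.** y(t) − y(t−1) = W y(t−1) +
Σₚ₌₂..d Dₚ y(t−p) + e(t). Channels are mean-centered per training segment;
the pooled training mean is stored and reapplied at prediction, which keeps
the R² baseline coherent without fitting intercepts. Structures: `dense`
(per-channel ordinary least squares), `sparse` (LASSO with weight λ on the
ℓ₁ norm; solved by coordinate descent via scikit-learn with predictors
standardized internally and coefficients returned on the original scale),
and `scalar` (W and all Dₚ diagonal — n decoupled scalar AR models). In
`diagonal` lag mode the higher-lag matrices are diagonal (AR form); in
`full` mode they are unrestricted (VAR form).

**Subspace state space.** The innovation-form model x(t+1) = A x(t) + w,
y(t) = C x(t) + v with noise covariance blocks (Q, M, R) is identified by
covariance-based stochastic realization: lagged output covariances Λᵢ are
pooled over training segments, the block-Hankel matrix H = [Λ_{i+j+1}]
(r future × s past block rows) is factorized by a truncated SVD into
observability (Γ = U S^{1/2}) and controllability (Δ = S^{1/2} Vᵀ) factors,
C and G = E[x(t+1) y(t)ᵀ] are read off their first blocks, and A follows
from the shift invariance of Γ. The steady-state one-step predictor gain K
solves the forward Riccati recursion, iterated from P = 0 to an update
tolerance of 1e−10 (at most 10⁴ iterations). Predictions run the stationary
filter x̂(t+1) = (A − KC) x̂(t) + K y(t) from zero initial state; the first
max(r, s) predictions are flagged as burn-in and excluded from scoring by
default. A data-matrix oblique-projection variant would differ only in the
SVD weighting; the covariance route was chosen for determinism and
reproducibility (no iterative likelihood, no projection conditioning
issues). The identified predictor must be strictly stable or fitting
refuses with diagnostics.

**Locally linear (manifold / model-on-demand).** For each query (the
stacked d own-lags at a test time), the regression surface is approximated
by a tangent hyperplane fitted by weighted least squares with Gaussian
weights k = exp(−‖xₘ − x_q‖²/2h²) over all training points; only the local
intercept is used, which equals the surface value at the query. The
weighted normal matrix is symmetric PSD, so the tolerance-truncated
pseudo-inverse (singular values below 1e−10 of the largest truncated) is
computed by batched eigendecomposition. Queries whose kernel weights all
vanish numerically (total mass below 1e−100, i.e. no training point within
reach) fall back to the global linear fit with a logged warning. h → ∞
recovers the global linear model to relative error < 1e−6 (tested). There
is no training phase; training time is reported as zero.

**MMSE (conditional expectation).** The minimum-mean-squared-error
predictor E[Δyᵢ | conditioning] is estimated by a Gaussian-window weighted
histogram: window standard deviation σ = β × (training range of the
conditioning variable), histogram over n_bins equal bins of the training
response range, normalized; the prediction is the histogram mean, which
equals the window-weighted mean of bin-center-quantized training responses.
Defaults β = 0.02, n_bins = 100, both exposed as hyperparameters. `pairwise`
mode conditions each channel's first difference on a single channel's
previous value (its own by default; a channel map gives cross pairs) with σ
set from the global training range; `scalar` mode conditions on the d
own-lags with Euclidean distance and the channel's own range. Queries with
zero histogram mass fall back to the unconditional mean with a warning.
Training time is zero (model on demand).

**MLP (NARX on first differences).** Input = stacked lags
(y(t−1), …, y(t−d)); output = y(t) − y(t−1). Architecture: D blocks of
[fully connected → batch normalization → ReLU → 50% dropout], a final fully
connected layer. Implemented directly on numpy (batched forward/backward
with standard batch-norm gradients), trained with minibatch Adam under a
fixed seed, cosine learning-rate annealing, a 10% validation split for
early stopping (patience 20) and a 200-epoch default cap. Inputs are
standardized; targets are scaled by their standard deviation *without* a
shift, so a network with its output layer forced to zero predicts a zero
first difference — exactly the zero-order-hold baseline (a tested
ablation). After training, batch-norm running statistics are recalibrated
exactly on the full training set, so evaluation reflects the fitted
function rather than the last minibatch. Weights and biases use uniform
fan-in initialization, which spreads ReLU breakpoints away from the origin
for low-dimensional inputs. The `identity` activation ablation turns the
network affine; it then matches the dense linear model's held-out R² within
0.05 (tested). The 50% dropout is a strong regularizer on narrow networks:
capacity tests on noise-free deterministic data disable it.

## Whiteness testing

The multivariate portmanteau statistic uses lagged residual
cross-covariances R̂(i) = (1/(N−M)) Σₜ e(t+i)e(t)ᵀ and
Q = (N−M) Σᵢ₌₁..M tr(R̂(i)ᵀ R̂(0)⁺ R̂(i) R̂(0)⁺), with a pseudo-inverse
(tolerance 1e−10) guarding near-singular lag-0 covariances. Because the
asymptotic χ² approximation is unreliable at these sample sizes, the null
is generated by randomization: the time indices of e(t) are shuffled 100
times (seeded), Q is recomputed for each, and the 95th percentile of the
shuffled values is the threshold Q_thr. Q/Q_thr ≤ 1 ⇔ whiteness not
rejected. The lag count defaults to M = min(20, ⌊N/5⌋). For univariate
residuals the Box–Pierce statistic N Σ ρ̂(i)² referred to χ²(M) is provided
(Ljung–Box small-sample correction behind a flag); it is cross-checked
against statsmodels in the test suite. Type-I error at the nominal 5% level
is verified by simulation (200 runs, exact binomial 99% band).

Q is invariant to channel permutations and to simultaneous invertible
linear recombination of channels when R̂(0) has full rank (tested to 1e−8).

## Cross-validation plans

* `fmri-like`: each recording is split into two halves; the segments form a
  leave-one-segment-out k-fold plan. Four 1200-sample scans give 8 folds
  with 600-sample test segments. For pairwise (per-channel-pair) methods a
  reduced plan keeps the second quarter of each segment (150 samples).
* `ieeg-like`: one fold per recording; the leading 80% trains and the
  trailing 20% tests (8 s / 2 s for a 10 s segment).
* `custom`: explicit train fraction.

Segments containing any non-finite value are dropped and reported by
`filter_nan_segments` before planning.

## Model comparison

Paired scores (methods × samples) are compared with one-sided Wilcoxon
signed-rank tests for every ordered pair (zero differences discarded per
Wilcoxon's rule; all-zero difference vectors give p = 1 by convention) and
Benjamini–Hochberg FDR control at α = 0.05 across the off-diagonal p
matrix. The BH mask is monotone in α (tested).

## Hyperparameter search

Stochastic hill climbing over a hypercubic mesh: each iteration evaluates
all 3^N candidates at {−step, 0, +step} per parameter (step 1 for integers,
1e−6 for reals), clipped to bounds and deduplicated; a cheaper coordinate
mode evaluates 2N+1 candidates. Every candidate is scored on a fresh,
independently drawn minibatch. Integer parameters jump to the argmax
candidate; real parameters take a bounded step learning_rate × scale ×
sign(central-difference slope) — the raw slope over a 1e−6 probe is
numerically unbounded, so the update uses only its sign, which makes the
procedure a normalized gradient ascent with a fixed step of 10% of the
parameter range by default. Ties keep the current state. The search stops
after a fixed iteration budget or when the state has not moved for 10
iterations. The incumbent (best seen) sequence is non-decreasing by
construction and is returned with the full trajectory.

## Synthetic data: what it emulates, and what it does not

* `gen_iid_tanh_ensemble` — N_ave independent unit pairs xᵢ(t) iid standard
  normal, yᵢ = tanh(xᵢ). Standard-normal inputs are a choice: zero-mean
  symmetric inputs keep the sigmoid centered in its nonlinear regime.
* `gen_sphere_correlated_ensemble` — unit positions uniform in the unit
  ball; jointly Gaussian rows with corr(xᵢ, xⱼ) = exp(−distᵢⱼ/ρ)
  (exponential decay is the simplest monotone kernel; the functional form
  is a choice). Cholesky with escalating jitter (1e−12 → 1e−5) handles the
  perfectly correlated ρ = ∞ limit.
* `gaussian_lpf` — unit-sum discrete Gaussian kernel with σ_t = 1/f_c − 1
  samples, truncated at ±4σ, reflective boundary; f_c = 1 is exactly the
  identity. The σ_t parameterization is a choice that makes the no-filter
  boundary case exact.
* `gen_colored_signal` — spectral synthesis with amplitude ∝ (1+k)^(−p/2)
  over integer rFFT bin indices k (finite DC), uniform random phases, unit
  sample variance. The log–log periodogram slope over the resolved band is
  −p (verified by a Welch-periodogram oracle).
* `add_noise_at_snr` — independent zero-mean Gaussian noise with variance
  var(signal)/SNR (SNR as a variance ratio).
* `gen_stable_var` — random sparse drift rescaled through the companion
  matrix so the lag polynomial's spectral radius meets the target exactly;
  10·n burn-in samples are discarded (empirically stationary for radius
  ≤ 0.95). The stationary covariance matches the discrete Lyapunov solution
  (tested at T = 10⁵).
* `simulate_izhikevich` — uncoupled quadratic integrate-and-fire neurons,
  v̇ = 0.04v² + 5v + 140 − u + I, u̇ = a(bv − u), reset (v, u) ← (c, u+d) on
  v ≥ 30 mV, plain Euler at dt = 0.1 ms, recorded samples clamped at 30 mV
  on spike steps. Input noise is iid Gaussian current noise per neuron and
  step (std 5 in the averaging demonstration — comparable to the drive
  I = 7, enough to desynchronize identical neurons). Neurons are uncoupled
  by design: this isolates the averaging effect; coupling is an extension
  point, not a modelled feature.

None of these emulate haemodynamics, volume conduction, preprocessing
artifacts, nonstationarity, or coupled network dynamics. Passing the
linearizing-mechanism checks on this suite shows that the *mechanisms*
behave as described on data that satisfy the generators' assumptions — it
does not by itself certify behaviour on real neuroimaging data.

## Linearizing-mechanism experiments

Each experiment sweeps one mechanism parameter with a paired-seed design
(the linear and nonlinear predictors always score identical data within a
repetition) and reports mean ± s.e.m. of the cross-validated R² of both
predictors. Static relations use 2-fold cross-validation; the
dimensionality experiment uses 5-fold. "Linear relationship" is
operationalized as a mean nonlinear-minus-linear gap below ε = 0.01 in R²
(`gap_threshold`); the manifold-vs-linear comparison in the dimensionality
experiment uses a 0.005 margin. Default grids: N_ave {1, 2, 3, 5, 8, 10,
20}; SNR {0.25, 0.5, 1, 2, 4, 8, 100} with the MMSE window widened as
β = 0.02 + 0.02/SNR; f_cutoff {1, 0.5, 0.2, 0.1, 0.05, 0.02}; p {0, 1, 2,
3}; n {1, 5, 10, 20, 40} with h swept over 7 logarithmic points in
[0.1, 10] and the best bandwidth chosen per fold by test R² (mirroring the
per-iteration sweep used to produce the optimal-window curves). Repetition
counts default to 20 seeds for the scalar mechanisms and 10 iterations for
the dimensionality and spiking-population experiments — sizes at which the
threshold estimates are stable across seeds on a single CPU.

The Izhikevich averaging demonstration bins the population-averaged
membrane potential at 1 ms, then compares a scalar AR-1 linear predictor
with the scalar MMSE predictor on the binned series over a 3 s default
(2 s in the test suite) simulation.

## Numerical choices and degenerate inputs

* Pseudo-inverse truncation: 1e−10 relative, everywhere (whiteness R̂(0),
  manifold weighted least squares).
* Ties in grid argmax/argmin: the smallest grid value wins (bandwidth
  sweeps); equal-objective candidates keep the current state (tuning).
* Constant test channels → NaN R² sentinel; constant conditioning ranges →
  degenerate-signal errors; all-NaN segment sets → empty-input error;
  non-finite simulated states → integration-failure error with step index.
* Binary matrix round-trips are bit-exact; delimited round-trips are
  accurate to 1e−12 relative (17 significant digits written).

## Known limitations

* Convolutional, recurrent and neural-mass model families are out of scope;
  the MLP, manifold and MMSE predictors provide the nonlinear coverage.
* The subspace implementation targets stochastic (output-only) modelling;
  there is no exogenous-input path.
* The MMSE pairwise mode returns one prediction per channel (own-lag
  conditioning by default); the full n × n pair matrix requires looping a
  channel map.
* The hyperparameter search is the mesh/coordinate stochastic hill climb
  described above, deliberately not a general-purpose optimizer.
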