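# Methods

## Model

`dfine` models a multivariate continuous-valued time series `y_t` (dimension
`n_y`, one observation vector per 50 ms step by convention) with two coupled
latent layers:

```
x_{t+1} = A x_t + w_t,          w_t ~ N(0, W)        dynamic latent factors (n_x)
a_t     = C x_t + r_t,          r_t ~ N(0, R)        manifold latent factors (n_a)
y_t     = f_theta(a_t) + v_t,   v_t ~ N(0, V)        observations (n_y)
```

The `(x, a)` pair is a linear-Gaussian state-space model; the decoder
`f_theta` (an MLP) bends the low-dimensional manifold factors into the
high-dimensional observation space. Keeping the *dynamics* linear while the
*embedding* is nonlinear is the central design choice: it buys exact, recursive
Gaussian inference on the manifold (Kalman filtering and RTS smoothing,
missing observations handled by pure forward prediction) while the autoencoder
absorbs the nonlinearity. An encoder MLP `f_phi : y -> a` produces the noisy
manifold-factor estimates that feed the filter; it is used for inference only
and is not part of the generative model. By default `n_x = n_a`.

## Learning

All parameters (A, W, C, R, mu0, Lambda0, encoder, decoder) are learned
jointly by minimizing the k-step-ahead prediction cost

```
L = sum_{k=1..K} sum_{t=1..T-k} MSE(y_{t+k|t}, y_{t+k}) + lambda_reg * L2(theta, phi)
```

where `y_{t+k|t} = f_theta(C A^k x_{t|t})` and `x_{t|t}` comes from a single
differentiable Kalman-filter pass over `a_hat = f_phi(y)`. The gradient flows
through the encoder, the filter recursion (including the gain/covariance
recursion), the k-step predictor and the decoder. This package implements the
backward pass with a small vectorized reverse-mode autodiff engine
(`dfine.autodiff`) written for exactly this graph; its gradients are verified
against central finite differences in the test suite (relative error < 1e-4,
typically ~1e-7). ELBO-style variational training is deliberately not offered.

Optimization uses Adam (initial learning rate 0.02, default 200 epochs,
optional multiplicative per-epoch decay, off by default), mini-batches of 32
segments, and `K` chosen so `K * dt >= 100 ms` (K = 2-4 at 50 ms;
`lambda_reg = 0.002`). Training assumes fully observed data; masks are honoured
at inference time only. Covariances W, R and Lambda0 are parameterized by
their log-diagonals so they remain positive definite at every gradient step;
A is unconstrained, and a warning is logged if its spectral radius exceeds 1
after training. The initial state (mu0, Lambda0) is reset per segment and
learned by default (a flag freezes it); its influence disappears once the
filter reaches steady state.

**Noise recalibration.** The prediction cost constrains the Kalman *gain* only
weakly: several (W, R) splits produce nearly the same filtered predictions,
but smoothing is sensitive to the split. After gradient training the package
therefore refines W, R, mu0 and Lambda0 by a few EM iterations on the encoder
outputs with A, C and the autoencoder frozen (`calibrate_noise`, on by
default). This leaves one-step prediction essentially unchanged and makes
smoothing consistently at least as accurate as filtering, as expected from
theory.

`V` does not appear in the cost and is not identifiable from it; it is
estimated post hoc from autoencoder residuals on the training split (diagonal)
and used only by generative sampling.

**Supervised variant.** When continuous behaviour `z_t` is available, a mapper
MLP `f_gamma : a -> z` is attached during training only and the cost gains
`lambda_beh * sum_t MSE(f_gamma(a_{t|t}), z_t)` (default `lambda_beh = 20`),
with `gamma` included in the L2 term. The behaviour term uses the *filtered*
manifold factor `a_{t|t}` (the mapper hangs off the manifold-factor node and
inference-time decoding uses dynamically inferred factors); a flag switches to
the raw encoder output. Latent inference is structurally identical for
supervised and unsupervised models — the mapper is never consulted.

## Inference

`infer_latents` z-scores the input with the training statistics, evaluates the
encoder at observed timesteps only (never at masked ones — no zero
imputation), runs the Kalman filter (and RTS smoother in smooth mode) with the
mask, and returns `x`, `a = C x` and the decoded `y_hat = f_theta(a)` at every
timestep including masked ones — this is the imputation path. Filtering is
strictly causal and recursive; processing a stream in chunks with carried
state is bit-identical to batch processing. Numerical policy: Joseph-form
covariance updates with explicit symmetrization, Cholesky solves with a 1e-9
jitter fallback (logged), 1-based time indexing in prose, 0-based in storage.

## MLP architectures

Encoder and decoder default to 3 hidden layers of 32 tanh units with a linear
output layer and biases everywhere (widths configurable). The decoder's output
layer is initialized small so an untrained model predicts near the (z-scored)
data mean — the chance level of the NRMSE metric. A is initialized at 0.95 I,
C with small N(0, 0.1) entries, W = 0.1 I, R = Lambda0 = I, mu0 = 0.

## Synthetic data

The simulators generate the study conditions used throughout the tests and the
acceptance script; they emulate noisy recordings whose population activity
lies on a low-dimensional manifold with lawful temporal structure, not any
particular biological circuit.

**Manifold sessions** (default 250 trials x 200 steps x 40 channels): a
driven walk in the intrinsic coordinates of a ring (radius 1), torus
(R = 2, r = 0.5) or Swiss roll ((u cos u, h, u sin u), u in [1.5pi, 4.5pi],
h in [0, 20]). Each trial drifts at a constant random velocity — roughly
0.75-1.5 traversals/revolutions of each coordinate per trial, random sign —
plus small Gaussian jitter; bounded coordinates reflect at their range ends,
angles wrap. A single trial therefore sweeps the manifold, which has two
consequences relied on elsewhere: the per-trial mean approximates the global
mean (so a constant predictor scores NRMSE ~ 1 per trial), and single-trial
latent point clouds contain the ring structure that the persistence metrics
look for. The 3-D trajectory is observed through a random 40 x 3 emission
matrix (first three rows identity, for undistorted 3-D visualization; all
quantification uses the full 40-D signal) plus white Gaussian noise. The
default noise sd is 0.4 x the RMS per-channel signal sd — "moderate" in the
sense that the true-model one-step NRMSE lands near 0.5, well between perfect
(0) and chance (1). Markedly larger noise makes adjacent whorls of the Swiss
roll ambiguous even for the true model. The exact parameterizations and
coefficients here are this package's own reconstruction choices and are all
configurable.

**Stochastic Lorenz sessions** (default 750 trials x 200 steps): Euler
integration (dt = 0.01) of the Lorenz system (sigma = 10, rho = 28,
beta = 8/3) with additive per-step Gaussian process noise of variance `q_var`
(supported range 1e-4 to 1), a 500-step noiseless burn-in from a
standard-normal start, and the same 40-D random emission with observation
noise variance 1.

**Data drops**: within every 100-step block of a test trial, exactly
`round((1 - rho) * 100)` whole observation vectors are removed uniformly at
random (`rho` = observed datapoint ratio), emulating wireless data drop.

**True-model reference**: an unscented Kalman filter (2n+1 sigma points,
alpha = 1e-3, beta = 2, kappa = 0) over the analytic generator of each trial
produces the true model's one-step-ahead predictions; on linear systems it
reproduces the Kalman filter exactly. What these simulations do *not* emulate:
spiking observations, non-stationarity, shared trial structure, behavioural
confounds — passing here shows correct learning and inference under the
model's own assumptions, not performance on real recordings.

## Evaluation

NRMSE (per dimension, root summed squared error over root summed deviation
from the mean, averaged across dimensions) is 1 for the per-dimension mean
predictor and 0 for a perfect one; constant dimensions are skipped with a
warning. One-step-ahead prediction uses `y_{t+1|t} = f_theta(C A x_{t|t})`.
Behaviour decoding: an MLP regressor (2 x 64 tanh, Adam, fixed seed — any
regressor meeting the contract may substitute) from smoothed latents for
continuous behaviour, scored by Pearson CC; for discrete classes, trials are
linearly interpolated to 400 points, sampled every 40th, flattened, and
classified by all one-vs-one Gaussian-kernel SVMs (kernel width by inner CV),
scored by mean ROC-AUC. Latent recovery for the Lorenz system fits a linear
map (plus intercept) from inferred factors to the true latents on training
trials and reports CC on test trials, absorbing rotation/scale indeterminacy.
All protocols use 5-fold cross-validation with z-scoring statistics from the
training folds only. 95% confidence bounds use the normal approximation of
the mean across folds/sessions (bootstrap optional).

**Persistence (TDA).** Vietoris-Rips H1 features are computed by
dimension-wise boundary-matrix reduction over Z/2 (union-find for
cycle-creating edges; triangle columns as integer bitsets). Point clouds are
z-scored per dimension first and subsampled to 100 points by default — the
triangle count grows as C(n, 3), and the pure-Python reduction is practical to
a few hundred points; the cap, the `max_radius` cutoff and pooled-vs-per-trial
aggregation are configurable. Per-trial features are computed and then
averaged within a test fold (pooling available). Ties in "most persistent" go
to the earlier birth.

## Problem sizes in the bundled protocols

The acceptance script trains one fold of one session per manifold type at 160
epochs with per-epoch decay 0.985 and latent dimension `n_a = n_x = 5` (a 3-D
linear system cannot carry two independent rotations, so the torus needs
n_x >= 4; the extra dimension is slack). The test suite uses one ring session
at 40 epochs, a 75-trial Lorenz session at 150 epochs (one tenth of the full
trial count), and a 120-trial torus session for the supervised comparison,
with behaviour tied to the torus minor angle — a feature weakly expressed in
the observations, which is exactly the regime where supervision should help.

## Known limitations

- Gaussian observation model only; no point-process/Poisson likelihoods,
  external inputs, or switching/locally linear dynamics.
- Single-session training; no multi-session joint fitting.
- The spectral radius of A is not constrained; strongly unstable learned
  dynamics would degrade long-gap prediction (a warning is emitted).
- The EM recalibration assumes the diagonal noise parameterization.
- The pure-Python Rips reduction is for modest point counts; it is exact, not
  approximate, but not optimized for thousands of points.
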