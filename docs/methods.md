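# Methods

## Preprocessing

Images are converted to grayscale with BT.601 luminance weights
(0.299, 0.587, 0.114) and optionally resized bilinearly (default target
240 × 320; set `resize_h = resize_w = 0` to keep native size — the phantom
benchmarks do, since resampling adds nothing when all inputs already share
one size). Global histogram equalization maps level g_k to
⌊G_k · (N−1)⌋ with G_k the cumulative histogram probability; flooring is
the standard convention and makes the map idempotent up to one gray level.
N is fixed at 256 unless the caller states otherwise. GHE exactly cancels
any monotone per-image intensity distortion (gain, offset, gamma); it does
*not* remove spatially varying shading, only the distribution-level part of
it.

## Wavelet features

The 2-D DWT uses symlets (least-asymmetric orthogonal Daubechies family),
default `sym4` — the smallest order in common use — configurable sym2–sym20,
at j = 4 levels: deeper splits leave too few approximation samples to carry
class information. Boundary handling defaults to `periodization`, the only
mode under which the discrete transform is orthonormal, so coefficient
energy equals image energy and the inverse transform is exact to float
precision; both properties are asserted in the tests, and symmetric padding
remains available for callers who prefer it. The feasible depth is
⌊log₂ min(h, w)⌋ (every subband keeps at least one sample); requests beyond
it raise an error naming the maximum.

Features:

* `rough` — the flattened level-j approximation grid. Detail subbands are
  excluded from features (they are noise-dominated) but retained in the
  tree for diagnostics such as mutual information.
* `freq` — one dominant-frequency estimate per subband plus their average
  f_avg. Each subband's estimate is the energy-weighted mean radial
  frequency of its 2-D DFT magnitude (DC excluded), divided by 2^level to
  express it in input-image cycles/pixel. The averaging count K is the
  subband count (13 at j = 4); f_avg is exactly the arithmetic mean of the
  per-subband values.
* `rough+freq` (default) — the concatenation.

A literal continuous-wavelet route is provided for 1-D signals:
`cwt_response` correlates the signal with ψ(t/a)/√a over a scale grid and
`estimate_frequency_cwt` returns f = f_c/(a*·δ) at the response-maximizing
scale, where the center frequency f_c is the dominant DFT peak of the
wavelet function on its support (δ = 1 sample). The signal is
Fourier-oversampled 4× before the scan so the discretized kernel stays
resolved at the smallest scales; the estimator recovers pure sinusoids over
0.03–0.35 cycles/sample within 10% relative error (the residual bias comes
from the spectral width of short symlets).

Mutual information between coefficient grids quantizes each grid into 64
equal-width bins over its observed range and evaluates the joint histogram
in bits. MI(A, A) equals the histogram entropy; monotone rescalings
preserve it.

## LDA

V_i in the between-class sum is the class sample count — the only reading
that makes the scatter identity total = VAR_W + VAR_B hold, which the tests
assert on random data. With rough-coefficient features the dimension
usually exceeds the per-fold sample count, so VAR_W is singular; the
projection solves (VAR_B, VAR_W + ridge·I) with ridge =
ε·trace(VAR_W)/r, ε = 1e−4 by default — small enough not to perturb the
well-posed case, large enough to dominate float noise. Eigenvalues are
sorted descending with a stable sort; each unit-norm row's first
non-negligible component is made positive so results are reproducible across
LAPACK builds. The output dimension is capped at c − 1 (the rank bound of
VAR_B); the pipeline default requests min(24, c−1), i.e. the full bound for
up to 25 classes.

## Logistic regression

All three objectives use the standard log(1 + exp(−y(Xᵀw + c))) data
term (a variant sometimes written without the "+1" inside the logarithm
is unbounded below and cannot be a loss, so the penalties share one term). The intercept is never
penalized. C multiplies the data term, so larger C means weaker
regularization. Labels are mapped internally to {−1, +1}; multiclass is
one-vs-rest by default, with a multinomial softmax sharing the penalty
machinery as an option.

The solver is proximal gradient descent with backtracking: the ℓ1 part is
handled by soft-thresholding (exact zeros; for small C the subgradient
condition zeroes the whole weight vector), the curvature condition uses the
quadratic majorization of the smooth part, and any step that would increase
the objective is rejected, so the recorded objective history is monotone
non-increasing. Defaults: tol = 1e−6 on the relative objective change,
max_iter = 1000; non-convergence raises a RuntimeWarning and flags the
model rather than failing. Features are standardized to zero mean / unit
variance using training data only (constants stored on the model) for
solver conditioning. Predictions normalize per-class sigmoid scores
(one-vs-rest) or use the softmax; ties resolve to the earliest label in the
sorted label set. Models serialize to JSON together with the
feature-configuration digest and refuse to predict when the digest
mismatches.

## Evaluation

Stratified n-fold cross-validation (default n = 10; the phantom benchmarks
use 5 so each class keeps 4 test images per fold) assigns each class's
shuffled samples round-robin to folds, so per-class fold sizes differ by at
most one and every sample is tested exactly once. Preprocessing and feature
extraction are per-image deterministic maps, so they are computed once;
everything fitted — LDA, standardization, classifier — is re-estimated per
fold from training rows only, which the poisoning test verifies.

Per-class collapse of the c × c confusion matrix gives Tp (diagonal), Fn
(rest of row), Fp (rest of column), Tn (remainder). Two metric variants are
reported because the `paper` variant's sensitivity formula, Tp/(Tp+Fp), is
conventionally precision: it is kept as the default for faithfulness to
the reported convention, `standard` uses Tp/(Tp+Fn). Zero denominators yield NaN
markers, never exceptions. The headline number is the average recognition
rate: the mean of the diagonal of the row-normalized percentage matrix.

## Phantom generator

Each class owns an oriented sinusoidal grating (distinct frequency and
orientation per class) plus a few Gaussian blobs; optional speckle
impulses, a linear illumination ramp in a random per-image direction with
random per-image gain/offset jitter (all scaled by the `illumination`
amplitude), and additive Gaussian or salt-and-pepper noise. All randomness
derives from (spec seed, class index, instance seed), so images are
bit-reproducible. Grating phase is jittered only slightly across instances:
anatomy does not translate freely between patients, and fully random phase
would make raw approximation coefficients incoherent within a class.

Default class frequencies span 0.015–0.035 cycles/pixel so the
class-defining signal lies inside the level-4 approximation passband
(|f| < 1/32 cycles/pixel), as anatomy-scale structure does in real MRI.
The default benchmark — 5 classes × 20 images at 128 × 128, Gaussian
σ = 10, illumination 0.3, seed 0 — is deliberately separable: it validates
the pipeline's mechanics (a run below 100% signals a regression), not
clinical difficulty. What passing it does *not* show: robustness to
registration error, anatomical variability, partial-volume effects,
bias fields with nonlinear profiles, or class overlap — real MRI cohorts
have all of these, and accuracy there cannot be inferred from phantom
results. The harsher shaded variant (illumination 0.8) is where disabling
equalization begins to cost accuracy.

## Numerical choices and limitations

* Equalization LUT flooring can differ by one level from a
  round-half-up convention; the tests allow exactly that slack where it
  matters (idempotence).
* The generalized eigensolver requires the regularized VAR_W to be positive
  definite; a singular matrix with ridge = 0 raises an error that names the
  remedy.
* The grid-search oracle for the logistic solver refines a dense 201×201
  grid three times; it bounds the solver's objective, it is not used in
  fitting.
* The CWT scale scan is a brute-force estimator intended for validation and
  diagnostics, not speed.
* The pipeline is 2-D slice-based; volumetric context is out of scope, as
  are denoising, bias-field correction, and registration.
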