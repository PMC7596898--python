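# Methods

`sparsebci` classifies two-class motor-imagery EEG (class 1 = right hand,
class 2 = right foot) through three stages: spatial filtering by common
spatial patterns (CSP), sparse-representation coding against a redundant
dictionary of training features, and classification either by minimum
class residual (SRC) or by a small residual convolutional network trained
on the sparse codes (FCRes-CNN). A seeded generator supplies synthetic
recordings with planted, known structure so every stage can be validated
end to end.

## Preprocessing

Continuous recordings (channels × samples, with cue markers) are segmented
into one epoch per cue over the half-open window `[onset, onset + T)`,
`T = round(epoch_seconds · fs)`; defaults are 3-s epochs at 100 Hz
(T = 300). Epochs are band-passed to 8–15 Hz — the mu-rhythm range in
which motor-imagery classes separate — with a 4th-order Butterworth filter
applied forward-backward (`scipy.signal.sosfiltfilt`). Zero-phase
filtering matters here because the next stage estimates epoch covariances;
phase distortion would bias them. Ocular/muscular artifact handling beyond
this band-pass is out of scope.

## CSP features

Per-trial covariances are trace-normalized (`X Xᵀ / tr(X Xᵀ)`) and averaged
within class, giving `C1`, `C2`. Filters are generalized eigenvectors of
`(C1, C1 + C2)`; the eigenvalue `λ_j ∈ [0, 1]` is the fraction of filtered
variance carried by class 1, and eigenvectors are normalized so
`w C1 wᵀ + w C2 wᵀ = 1`. With `n_filters = 2h` requested, the `h` largest-
and `h` smallest-λ filters are kept (default total 32; capped at the
channel count when fewer channels exist, with the actual count recorded).
When the composite covariance is near-singular (condition number > 1e10,
likely with many channels and few trials) a shrinkage
`C ← (1−γ)C + γ (tr C / ch) I`, γ = 1e−6, is applied with a warning.
Filter signs are fixed so each filter's largest-magnitude coefficient is
positive, making outputs deterministic.

The per-epoch feature is `log(var(w_j x) / Σ_k var(w_k x))` — log of
normalized band power. The log is the default because it makes features
approximately Gaussian; raw normalized variances are available via
`log=False`. Spatial *patterns* (mixing directions) are computed as
`Cc Wᵀ`, which is correct for reduced filter sets where the pseudo-inverse
of `W` is not.

## Sparse-representation classification

Training features are stacked column-wise, grouped by ascending class and
unit-L2-normalized, forming the redundant dictionary `A ∈ R^{m×N}` (m
features, N training atoms, m < N in the intended regime). Test features
are unit-normalized with the same convention. A test vector `y` is coded by

    min ‖x‖₁  subject to  ‖A x − y‖₂ ≤ ε,

the equality-constrained ideal relaxed by ε to absorb noise; ε defaults to
`0.01 ‖y‖₂`. The class residuals `r_i(y) = ‖y − A δ_i(x̂)‖₂` (δ_i keeps
only class-i coefficients) decide the label by `argmin_i r_i`, ties toward
the lower class index.

**Solver.** FISTA (accelerated proximal gradient) on the Lagrangian form,
with a per-sample penalty sweep: the penalty starts at half the maximum
atom correlation and shrinks (×0.2, floor 1e−12 of the start) until the ε
constraint is met, warm-starting between sweeps; iterate-change tolerance
1e−8 (relative), per-sweep cap `max_iter` = 5000. A final nested-support
polish re-fits least squares on prefixes of the atoms ranked by
|coefficient| and keeps the feasible candidate of smallest L1 norm; this
removes the soft-threshold bias near the constraint boundary and is what
lets the solver reach exact basis-pursuit optima at ε = 1e−8 (verified in
tests against an exact linear-programming solution and exhaustive support
enumeration). All samples are solved in one vectorized batch.

**Leave-one-column-out coding.** Sparse codes of training samples (the
network's training input) are computed with the sample's own dictionary
column forced to zero, since self-coding would leak a perfect atom. The
constraint is exact: the proximal step of L1 plus a coordinate-zero
constraint is separable, so masking the iterate each iteration solves the
reduced problem. Self-inclusive coding is available via the
`exclude_columns=None` default in `sparse_features`.

**Benchmark instances.** The solver's oracle-equivalence test draws random
6×12 unit-column Gaussian dictionaries with 2-sparse targets restricted to
instances satisfying the exact recovery condition
`max_{j∉S} ‖A_S⁺ a_j‖₁ < 1` — an a-priori property of the instance under
which basis pursuit provably recovers the planted support. Without this
restriction roughly one in six random instances has a denser solution of
strictly smaller L1 norm, so support recovery would measure the instance
ensemble, not the solver.

## FCRes-CNN

The network consumes a sparse code as a length-N single-channel sequence.
Architecture: a fast down-sampling module — convolution with stride 3
(kernel 7, 16 filters) in place of pooling, then dropout and batch
normalization — three residual modules, and a classification module. Each
residual module is two serial convolutions (kernel 3; 16/32/32 filters per
module, batch-normalized, ReLU between) with an identity shortcut, so the
branch learns only the residual `F(x) = H(x) − x`; a width-1 projection
convolution stands in for the identity when channel counts change. Dropout
(rate 0.3 wherever a dropout layer appears) and max-pooling (size 2) follow
the shortcut addition. The head is a width-1 convolution reducing to 8
channels, flatten, dropout, and a dense softmax.

Training minimizes categorical cross-entropy with Adam at learning rate
0.001 for 300 epochs by default; the configured batch size of 2,500
exceeds typical trial counts and therefore degrades to full-batch
gradient descent. Filter counts, kernel sizes, dropout rate, optimizer and
epoch count are configuration surface with the defaults above — chosen as
the smallest sizes consistent with the module inventory and a
few-hundred-trial training set (about 1.4·10⁴–10⁵ parameters depending on
input length).

The implementation is plain NumPy with explicit forward/backward passes
for every layer (verified against finite differences) and a single integer
seed driving weight initialization, dropout masks and shuffling — two runs
with the same seed, data and config produce identical histories, and
seeded evaluation reports are byte-identical.

## Evaluation protocol

Accuracy is `100·(TP+TN)/(TP+TN+FP+FN)` with class 1 positive; loss is
categorical cross-entropy with probabilities clipped at 1e−12. The split
protocol shuffles all trials once under a seed and holds out the last
`n_test` (default 100 of 280) as the test set, unstratified. CSP and the
dictionary are fitted on the training split only. For the comparison
curves the residual classifier needs a probability output; residuals are
mapped through a softmin with temperature 0.1 (residuals of unit-norm
features lie in [0, 1], so this gives non-degenerate probabilities). This
mapping is an interpretation of ours, used only for the loss curves.
Repeated evaluation averages over shuffled splits (`--seeds` in the CLI).

## Synthetic generator

Each trial superimposes two sources mixed along two orthonormal spatial
patterns (drawn once per seed) onto spatially correlated 1/f noise whose
mixing matrix is also drawn once per configuration, keeping the noise
stationary across trials as CSP assumes. A source is an
amplitude-modulated 10 Hz sinusoid with per-trial random phase and a slow
(0.2–0.6 Hz) envelope, unit variance before scaling. Class 1 carries
`class_power_ratio` × the variance along pattern 1 (class 2 along pattern
2); ratio 1 is the non-identifiable null. Defaults (10 channels, 140
trials per class, 100 Hz, 3-s epochs, ratio 10) mirror the intended study
scale at desk cost.

What the generator does *not* emulate: volume conduction from a realistic
head model, non-stationary noise, eye-blink/muscle artifacts, inter-trial
rhythm variability beyond random phase/envelope, or inter-subject
variability. Passing tests therefore demonstrate correctness of the
algorithms under the model's assumptions, not expected accuracy on real
recordings.

## Problem sizes used in the test suite and acceptance script

The full-scale run uses 140+140 trials with the last-100 held-out split
and default network settings. The chance-level ensemble (ratio 1) uses 20
seeds at a reduced size — 70+70 trials, 60-trial test split, 40 network
epochs — chosen because chance behaviour is insensitive to training length
and trial count while the ensemble stays desk-scale. Property tests use
30–40 trials per class. At small trial counts the network undertrains
relative to the residual baseline; the directional comparison between the
two classifiers is asserted only at the full-scale configuration.

## Known limitations

- Strictly two-class; no one-vs-rest extension, no filter-bank CSP.
- No dictionary learning or weighted-SRC variants.
- The FISTA penalty sweep can declare non-convergence on pathological
  inputs (flagged on the returned code, with a warning).
- The NumPy network trains on CPU at desk scale only; no GPU path.
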