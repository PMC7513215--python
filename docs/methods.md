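# Methods

## Sample entropy

For an epoch `x(1)…x(N)` with embedding dimension `m` and tolerance `r`, form
the `T = N − m` templates `X_m(i) = (x(i), …, x(i+m−1))`. `B` counts ordered
template pairs `i ≠ j` whose Chebyshev distance `max_k |x(i+k) − x(j+k)|` is
strictly below `r`; `A` is the same count with the templates extended to
length `m + 1` (the same `T` templates at both lengths, so every template has
a defined extension). Sample entropy is `−ln(A/B)`. Conventions that matter:

- **Self-matches are excluded** at both lengths; including them biases the
  statistic toward zero.
- **Tolerance** is `r = r_factor · SD` with the *population* (divide-by-N)
  standard deviation of the epoch; defaults `m = 2`, `r_factor = 0.25`.
  Because `r` scales with the data, the statistic is invariant under affine
  amplitude transforms `x → a·x + b`, which the suite asserts.
- `A = 0` or `B = 0` raises an undefined-entropy error rather than returning
  an arbitrary number; zero-variance epochs raise a degenerate-input error.
  Silent placeholders would poison the downstream eigenanalysis, so
  imputation (by the channel's epoch-wise median) is strictly opt-in.
- The tolerance SD is computed **per epoch**, not per recording: each epoch
  is treated as its own stationary segment, and this keeps the feature well
  defined when gain drifts between epochs.

Two implementations coexist: a numba-compiled pair loop with early
abandonment (used when numba is importable) and a vectorized numpy path; a
regression test pins them together, and both are validated to ≤1e−12 against
a brute-force oracle that builds explicit template matrices and scipy
Chebyshev distances.

Fuzzy entropy replaces the hard threshold by the graded membership
`exp(−d^n / r)` evaluated on mean-centred templates (gradient `n = 2` by
default), averaged over ordered pairs at lengths `m` and `m + 1`; the result
`ln φ_m − ln φ_{m+1}` is finite for any epoch with positive variance.

Combination entropy is exposed as a registry slot because the composite
estimator it refers to is defined elsewhere and not standardized; the shipped
default — the mean of sample and fuzzy entropy — is a clearly labelled
stand-in that users replace via `set_combination_estimator`.

## PCA, kernel PCA and component selection

Linear PCA standardizes columns (mean 0, SD 1 with the N−1 divisor) and
eigendecomposes the feature **correlation** matrix, so each channel enters
with equal weight regardless of its entropy variance; a covariance variant
was deliberately not made the default to keep the reduction scale-free.
Loading vectors are unit norm with the first nonzero entry made positive, a
tie-break that makes signs (and therefore serialized models) reproducible.

Kernel PCA evaluates the Gram matrix `K_ij = k(x_i, x_j)` (through
scikit-learn's pairwise kernels), double-centres it,
`K̃ = K − 1K − K1 + 1K1` with `1` the matrix of `1/M` entries, and solves
`K̃a = μa`. Dual coefficient vectors are scaled so each feature-space
component has unit length (`μ‖a‖² = 1`); training scores are then `μ·a` and a
new sample's score on component `k` is `Σ_j a_jk k̃(x_j, x_new)` with the test
kernel rows centred using the **training** column/grand means. Projection of
the training set therefore reproduces the fit-time scores exactly, and with a
linear kernel on standardized input the scores coincide with correlation-PCA
scores up to sign — both are asserted.

Numerical choices:

- Eigenvalues below `max(μ) · 1e−10` are truncated before contribution rates
  are computed. The mlp/sigmoid kernel is not positive semidefinite, so
  genuinely negative eigenvalues occur; they are truncated and counted, and
  contribution rates are defined over the retained non-negative spectrum.
- The RBF kernel is `exp(−‖x−y‖²/δ²)` (squared distance); an unsquared
  variant is available via `KernelSpec(squared=False)` for users whose
  convention differs.
- Fractional polynomial orders (e.g. `P = 0.5`) require `x·y + 1 ≥ 0` and
  raise a configuration error otherwise; entropy features are non-negative,
  so this holds in the intended use.
- `cvc_select` returns the smallest `k` whose cumulative contribution reaches
  the threshold, with a `1e−12` epsilon so that rates quoted as rounded
  decimals whose float sum lands a hair under a round threshold (a case that
  occurs in the bundled published profiles) are not off by one. If the total
  never reaches the threshold, all components are kept with a warning.
- **KPCA input is used raw by default** (`standardize_features=False` in the
  pipeline). Entropy features already share a common nats scale, and the RBF
  width default `δ = 0.2` is meaningful on that scale: z-scoring 30 features
  first inflates typical pairwise distances to ~√60, which drives
  `exp(−d²/0.04)` to underflow and degrades the Gram matrix toward the
  identity. PCA, by contrast, standardizes internally as part of the
  correlation-matrix construction. A flag enables standardization before
  KPCA for users whose features are on heterogeneous scales.

## Classification protocol

The motivating protocol quotes both 3-fold cross-validation and a 70/30
split, which are mutually inconsistent; the default here is stratified
3-fold CV (each fold ≈ 67/33), with a single stratified 70/30 holdout
available as `protocol="holdout"`, and every report names the protocol used.
Reduction is fitted per training split only; held-out rows are projected
with stored training statistics. A canary test randomizes held-out labels
after fold assignment and asserts the training-fold fit is bit-identical —
the observable signature of leak-freedom.

The SVM stage is a support-vector classifier with RBF kernel, unit
regularization (`C = 1`) and inverse-feature-count kernel scale
(`gamma="auto"`), all exposed in `PipelineConfig`; these were fixed as
documented defaults rather than tuned per dataset. Accuracy is the
arithmetic mean of fold accuracies, rendered at 2 decimals. Fold assignment
is stratified by epoch row; subject-grouped splitting can be imposed by
passing explicit folds to `run_pipeline`.

## Synthetic data

`SimSpec` defaults describe the study conditions the toolkit targets: 10
subjects, 30 channels at 1000 Hz, 30 s of alert followed by 30 s of fatigue
per subject, epoched at 1 s — a 600 × 30 labelled entropy matrix (15 subjects
give 900 × 30). Alert channels are white noise (SD 1.0) plus a weak 8–13 Hz
sinusoid (amplitude 0.3); fatigue channels invert the balance (oscillation
2.0, noise 0.4). Per-subject and per-channel log-normal gain jitter (SD 0.05)
perturbs the oscillation and noise gains independently, so the
oscillation-to-noise ratio — and hence the entropy — varies across channels
and subjects while amplitude-only changes cancel by the entropy's affine
invariance. The `contrast` dial linearly interpolates the fatigue recipe
toward the alert recipe; at 0 the states are identically distributed and the
pipeline must fall to chance, which is asserted against the 95% binomial
band of 50%.

What the generator does *not* emulate: 1/f background spectra, spatial
correlation between electrodes, artifacts, non-stationarity within a block,
or inter-subject variability beyond gain jitter. Passing tests therefore
demonstrate that the pipeline recovers a complexity contrast when one exists
and not that any particular accuracy transfers to real EEG; the bundled
published contribution-rate profiles (`sekpca.profiles`) are the only
real-data fixtures, and they exercise component selection only.

## Problem sizes

The end-to-end checks run the full default dataset (600 epochs × 30 channels
× 1000 samples, two generator settings), chosen as the smallest configuration
that matches the study layout; oracle sweeps use 50 epochs of 50–1000 samples
and 20 seeded 30×5 matrices for the algebraic KPCA checks.

## Known limitations

- Combination entropy's default is a stand-in, not the literature estimator.
- The EDF reader is a thin wrapper over mne and is exercised only for its
  error paths in the suite (no EDF writer is available to round-trip against).
- KPCA stores the training rows in the fitted model (required for
  out-of-sample kernels); models scale with the training-set size.
- No kernel-parameter auto-tuning beyond explicit grids via
  `compare_methods`; no incremental/sparse KPCA; no pre-image reconstruction.
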