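# Methods

## Normative model

Each brain-derived feature is modeled independently (one model per
column). The response is passed through a sinh-arcsinh warp composed with
an affine standardization,

    φ(y) = sinh(δ · asinh((y − μ)/σ) − ε),

where μ and σ are fixed at the training mean and SD of the response, ε
controls skew and δ > 0 controls tail weight; ε = 0, δ = 1 recovers the
identity up to standardization. The warped response follows a Bayesian
linear regression with isotropic Gaussian weight prior (precision α) and
Gaussian noise (precision β). The log marginal likelihood — including the
warp Jacobian Σ log φ′(yᵢ) — is maximized over (log α, log β, ε, log δ)
with L-BFGS-B from three deterministic starts (ε ∈ {0, ±0.7}) to avoid
local optima in the skew direction; an eigendecomposition of XᵀX makes
each evidence evaluation O(n·d). Given the hyperparameters, the weight
posterior N(m, S) is closed-form, and

    Z = (φ(y) − xᵀm) / sqrt(β⁻¹ + xᵀSx)

is the deviation score. Because the warp is strictly monotone, Z is
strictly increasing in y at fixed covariates, and Z = 0 exactly at the
predicted median.

The warp acts on the whole response, whereas skewness in real (and
simulated) data typically enters through the residual; the model is
therefore an approximation whose adequacy is judged by the calibration of
held-out control scores (mean ≈ 0, sd ≈ 1, reduced |skew| relative to an
identity-warp fit), which the test suite checks directly.

### Design matrix

Deterministic column order: intercept; cubic B-spline in age with 5
interior knots at training-age quantiles; sex (0/1); one scalar
image-quality metric (Euler-like for structural features, mean-FD-like
for functional ones), linear; reference-coded site indicators (first site
by sorted label dropped). Outside the training age range the spline
columns continue linearly (first-order expansion at the boundary) rather
than polynomially — extrapolation stays tame, but transfer cohorts are
expected to lie inside the reference age support, as in practice.

### Fit metrics

Explained variance EV = 1 − var(φ(y) − mean)/var(φ(y)) in warped space;
MSLL = mean[−log predictive density + log density under a Gaussian with
the training mean/variance] (more negative is better; 0 for a model no
better than the trivial baseline); skew and excess kurtosis of Z.

### Transfer to unseen sites

A pre-trained model set is adapted to a new scanner from ≥ 10 control
subjects of that site: their uncalibrated scores define a per-feature
mean shift and variance scale, and subsequent scoring applies
Z′ = (Z − shift)/√scale. Both mean and variance are recalibrated —
per-site noise scales are a designed feature of the synthetic cohorts and
common in practice. The equivalent adjustment of the predictive
distribution (mean + shift·sd, variance × scale) is used when computing
fit metrics, so scores and metrics always agree. Transfer returns a new
model-set object; the original scoring of known sites is untouched. With
n_adapt = 100 the calibration estimates carry sampling noise of order
0.1 on the shift; post-transfer scores inherit it.

## Benchmarks

* **Task 1 (group differences):** two-sided pooled-variance t-tests per
  feature (Welch optional), Benjamini–Hochberg step-up across features,
  count of adjusted p < 0.05. Features with zero within-group variance in
  both groups get undefined p and are excluded from the count with a
  warning. Extreme deviations are counted per feature with strict
  thresholds (Z > 2, Z < −2), separately per tail and group; group count
  vectors are compared with a Mann–Whitney U test (exact enumeration for
  tie-free combined n ≤ 20, tie-corrected normal approximation
  otherwise), because count distributions are skewed.
* **Task 2 (classification):** linear-kernel SVC, fixed C = 1 (no
  tuning), stratified k-fold CV (default 10) seeded for reproducibility;
  held-out subjects scored with the decision function, summarized as
  fold-mean ROC AUC.
* **Task 3 (BBS regression):** PCA on the centered training matrix (no
  per-feature scaling; scaling exposed as an option upstream of the
  call), top k = 15 expression scores, OLS with intercept; the
  prediction for a test subject is the dot product of the fitted
  coefficient vector with the subject's expression scores; metric is
  test-set MSE. With k equal to the full rank this reduces to OLS on the
  raw features (tested).

## θ and the permutation test

θ is oriented so positive always favors deviation scores. The test is
one-sided by construction: C counts θ_perm ≥ θ_obs and
p = (C+1)/(n_permutations+1) exactly — the minimum attainable p is
1/(n_permutations+1). Permutations are sampled with replacement from the
permutation group. Each iteration shuffles only the outcome labels
(diagnosis for tasks 1–2, cognition for task 3) and applies the same row
permutation to both feature arms; the feature matrices are never permuted
and normative models are never refit, since labels play no role in their
estimation. Fold assignments (task 2) and the train/test split (task 3)
are computed once from the observed labels and reused across iterations,
isolating label exchangeability as the null hypothesis. Under a permuted
labeling a held-out fold can be single-class (probability ~2·10⁻³ per
fold at the default sizes); such folds are dropped from that iteration's
fold mean. For speed, the permutation runner trains each fold through
libsvm on a precomputed per-fold Gram matrix and computes AUC by the
rank-sum identity; the suite asserts numerical identity with the public
`SVC(kernel="linear")` path across arbitrary relabelings. Default
n_permutations is 499 for routine runs; 10,000 is appropriate for final
analyses and is a config switch.

## Synthetic study conditions

The generator emulates the structure of multi-site clinical imaging
studies; its defaults are the package's study conditions.

* **Sites:** 4 sites × 150 subjects; nested distinct age windows
  ((6, 85), (10, 80), (14, 75), (18, 70)) — wide lifespan reference
  cohorts plus narrower adult cohorts contained in them, so transfer
  never extrapolates in age; additive site offsets ~ N(0, 1²) and
  multiplicative noise scales exp(N(0, 0.3²)).
* **Age trends:** per feature, a logistic developmental rise (amplitude
  U(2, 5) noise-SD units, center U(10, 25) y, steepness U(3, 8) y) plus a
  linear late-life decline (slope U(0.01, 0.04)/y past an onset
  U(30, 50) y) — smooth lifespan trajectories a quadratic fit
  underfits but a spline captures.
* **Covariate effects:** sex ~ N(0, 0.3), quality metric (gamma(3, 1.2)
  distributed) with small linear effect N(0, 0.05) per feature.
* **Noise:** unit SD, optionally skewed by the inverse sinh-arcsinh map
  sinh(asinh(G) + s) standardized by Gauss–Hermite moments; default
  s = 0.5 (mildly right-skewed), exercising the warp-estimation path.
* **Patients:** overall fraction 0.25 with site-structured recruitment —
  shares (…, 0.05 split over reference sites, 0.15, 0.8) so the last
  site is the case-heavy clinical site. This site–diagnosis confounding
  is deliberate and realistic: it is the regime in which residualizing
  site out of raw features absorbs part of the group effect, while the
  normative model calibrates each site from its controls only and
  preserves it. Patients carry a shared shift of −0.6 noise-SD on a
  random 30% of features plus heterogeneous individual deviations: 5
  features per patient, drawn independently per patient, each shifted
  −1.5 — spatially non-overlapping individual effects. Patient counts
  equal round(fraction × N) exactly.
* **Connectomes:** subject truth lives in Fisher z-space (population edge
  means N(0.25, 0.25), edge-wise age slopes, attenuated site offsets,
  patient effects scaled by the subject SD 0.2); correlations are tanh of
  the z edges, so matrices are exactly symmetric with unit diagonal and
  off-diagonals strictly inside (−1, 1); runs add z-space noise
  (default SD 0.1). Run matrices are Fisher-transformed then averaged
  (the order is configurable; the operations agree in the low-noise
  limit).
* **Cognition:** standardized projection of the features onto random
  loadings plus Gaussian noise (SD 0.5), restandardized.

What the generator does *not* emulate: voxel/vertex images, scanner
physics, motion artifacts, realistic effect-size calibration to any
specific clinical cohort, longitudinal structure, or missing data.
Passing benchmarks on these cohorts demonstrates the pipeline's internal
correctness and the direction of the deviation-score advantage under
site-confounded recruitment — not effect sizes on any real dataset.

## Pipeline

Training uses controls from the first `n_training_sites` (default 2)
sites only. Each benchmark site's controls are split in half: one half is
the transfer adaptation sample, the other half joins the benchmark sample
with the site's patients (no subject serves both calibration and
benchmarking). The raw arm residualizes the benchmark sample's features
on intercept, sex, site, age, age² (+ motion, motion² for the connectome
modality) by pooled least squares. Task 3 uses the benchmark controls
only, split half/half into train/test. All randomness derives from the
run seed through named SeedSequence children; a run is a pure function of
(config, seed). Reports refuse to serialize any row whose p-value
violates the counting formula.

## Problem sizes in reported runs

The default suite (and `scripts/acceptance.py`) uses 600 subjects, 20
structural features, an 8-network connectome (28 edges), and 499
permutations; Monte-Carlo validity checks use 200 repetitions of a
100-subject null with 199 permutations, and power checks use 20 seeded
repetitions of the default cohort. These sizes make the whole analysis
reproducible on a laptop CPU in minutes while leaving every statistical
contract testable.

## Known limitations

* One noise precision per model: within-site age-dependent
  heteroskedasticity is not modeled (the warp handles shape, transfer
  scaling handles per-site variance).
* The sinh-arcsinh warp acts on the marginal response rather than the
  residual; under strong covariate effects the estimated ε/δ compromise
  between residual shape and trend curvature.
* Fixed-effect site indicators do not pool across sites; sites with very
  few training controls get noisy offsets (hierarchical pooling is out of
  scope).
* Permutation runners reuse fold/split assignments; re-randomizing folds
  inside each permutation would test a slightly different null and was
  not chosen.
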