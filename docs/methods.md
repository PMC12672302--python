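# Methods

## Trajectory model

An eye's mean-deviation (MD) series is modeled as a sparsely observed random
function over a 10-year domain (t in days, [0, 3650]):

    Y_ij = mu_c(t_ij) + sum_k xi_ik phi_k(t_ij) + eps_ij,
    xi_ik ~ N(0, lambda_k),  eps_ij ~ N(0, sigma2)  i.i.d.

with stratum-specific mean mu_c (c = fast/slow progressor), shared orthonormal
eigenfunctions phi_k (unit L2 norm over the domain in days), decreasing
variances lambda_k (dB²·days), and white measurement noise sigma2 (dB²).
K = 2 components are used throughout. Assumptions worth keeping in mind:
deviations from the stratum mean are smooth and low-rank; noise is
homoscedastic; observation times are non-informative (no sicker-visit-sooner
feedback).

## Synthetic cohort generator

The generator emulates the cohort structure the pipeline assumes, with the
published cohort characteristics as defaults:

- **Phenotypes.** Each eye is fast with probability 0.0892, i.i.d.; mean
  trajectories are linear with slopes −2.51 (fast) and +0.20 dB/year (slow)
  from a common baseline level −5.11 dB.
- **Modes.** phi1 is flat (a persistent eye-to-eye MD offset), phi2 one cosine
  cycle over the domain (slow oscillation). lambda1 is derived so the flat
  mode reproduces the cross-eye baseline-MD spread of 6.33 dB:
  lambda1 = (6.33² − sigma2)·3650 ≈ 1.4e5 dB²·days. lambda2 = 6000 dB²·days
  puts a visible but secondary oscillation (≈1.8 dB SD at the cosine extremes,
  ≈4% of variance) on top of the dominant flat mode, matching the
  flat-first-mode regime qualitatively. sigma2 = 1.0 dB² is a typical MD
  test–retest noise level.
- **Visit schedules.** First test at day 0; per-eye follow-up span lognormal
  with median 1651 d (log-SD 0.715, reproducing the reported Q3 ≈ 2674 d),
  capped at the domain; inter-test gaps lognormal with a scale constant
  calibrated once by simulation so the median test count is 4. A visit_rate
  of 1 forces the degenerate single-visit schedule.
- **Covariates.** Continuous baseline features (VA, IOP, CDR, CCT, spherical
  equivalent, age) use per-class means/SDs; race/sex use per-class category
  frequencies; four binary medication/diagnosis indicators receive additive
  log-odds shifts for fast-class patients, calibrated once toward a Stage-1
  AUROC of 0.77. Note the achievable AUROC against *measured* labels
  saturates near 0.68 regardless of effect size: at a median of 4 noisy
  tests, a sizable share of measured-fast labels are slope-noise artifacts on
  true-slow eyes whose covariates carry no class signal. Spherical equivalent
  is missing at 27%, other numerics at 0.5%, race at 1.3%.
- **Patients.** A patient contributes two eyes with probability 0.72; eye
  scores share a patient-level random effect (correlation 0.5); patient
  covariates link to the patient's worst-eye class. Neither the inter-eye
  correlation nor the visit-interval law is known for real cohorts — both are
  documented stand-ins.
- **Excludable records.** Unreliable tests, 10-2 patterns, post-surgical tests
  and minority-strategy tests are injected as extra rows at small rates so the
  eligibility filters operate on realistic input.

What the generator does **not** emulate: pointwise 54-location threshold maps,
MD floor/ceiling effects in advanced disease, post-surgical trajectory
changes, informative visit timing, or a continuous slope distribution — real
"fast" eyes are a thresholded tail of a continuum, whereas the generator draws
two discrete phenotypes. Passing tests therefore demonstrate correctness of
the machinery under the assumed generative model, not clinical performance.
One visible consequence of the discrete-phenotype choice: Tukey fencing on
slopes clips part of the well-separated fast mode (several percent of eyes),
far more than the handful of outliers a continuous empirical slope
distribution yields.

## Cohort pipeline

Record filters (fixation loss < 0.33, false negatives < 0.33, white
background, no 10-2 pattern, age ≥ 18, no prior glaucoma surgery) →
per-eye majority-(strategy, stimulus) resolution, ties kept with the
chronologically first test → ≥3 tests per eye → per-eye OLS MD slope in
dB/year (days/365) → patient-level 80:10:10 split (seeded permutation,
floor-of-cumulative-ratio block sizes) → Tukey outlier removal on slopes →
strict labeling: fast iff slope < −1.0.

Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR; quantiles by linear interpolation
of order statistics) are computed on *training-split* slopes and applied to
all splits, so that no trained artifact can depend on validation/test data;
the standalone `tukey_outlier_filter` remains split-agnostic. The baseline
window is [0, 365] days inclusive. Stage-1 features per eye: earliest
baseline MD/PSD, baseline test count, within-baseline OLS slope when ≥2
baseline tests (else 0 plus an indicator column), the patient's EHR numerics
(training-mean imputation) and one-hot categoricals (missing race → "Other";
levels unseen in training raise an error naming the column).

## Sparse FPCA estimation

1. **Mean.** Local-linear Epanechnikov smoothing of all pooled (t, MD)
   points, evaluated on the 100-point output grid. Bandwidth "auto" is GCV
   over a geometric grid spanning 5–50% of the domain, computed on binned
   data with the within-bin sum of squares kept in the numerator (dropping it
   silently removes the complexity penalty). Windows without data widen
   locally (×1.5 per step, with a warning).
2. **Covariance.** Raw off-diagonal residual cross-products are binned onto a
   51×51 grid and smoothed with a local *quadratic* surface (a local plane
   attenuates the curvature of oscillatory modes too aggressively). Because
   cross-products of one eye share its scores, their errors are strongly
   correlated and GCV undersmooths badly; the surface bandwidth is instead
   chosen by subject-level 3-fold cross-validation over the same candidate
   grid. sigma2 is the average over the central 50% of the domain of the
   positive part of (smoothed diagonal of squared residuals − surface
   diagonal).
3. **Eigenanalysis.** Quadrature (trapezoid) eigendecomposition of the
   surface; negative eigenvalues truncated and excluded from the fraction of
   variance explained; eigenfunctions unit-norm with nonnegative integral
   (first nonzero value positive on a zero integral); interpolated to the
   output grid and re-orthonormalized by Gram–Schmidt under the output
   quadrature.
4. **Reduced-rank ML refinement.** The kernel estimates initialize an EM
   iteration over the K-component random-effects model, with the mean and
   eigenfunctions parameterized on a coarse piecewise-linear basis
   (13 knots, reduced to about one knot per five subjects for small strata).
   The E-step computes each eye's posterior score moments; the M-step solves
   one joint linear system for the mean and component coefficients with a
   mild second-difference ridge (1e-3 of the data scale) that keeps knots
   without local support on the linear continuation of their neighbors; the
   representation is re-canonicalized (orthonormal, decreasing variances)
   each iteration. EM runs to a 1e-5 relative-change tolerance (cap 300).
   The refinement exists because the kernel eigendecomposition, while
   consistent, is statistically inefficient for weak components under sparse
   designs; with it, the weak second mode is recovered an order of magnitude
   more accurately at 500 eyes with a median of 4 visits. Setting
   `em_iterations=0` falls back to the kernel estimates (with an optional
   least-squares eigenvalue refit). A sanity guard compares the model-implied
   domain-averaged variance (sum(lambda)/|domain|, by orthonormality) with the
   observed mean squared residual: small heterogeneous strata can push the
   Gaussian ML toward a degenerate high-variance ramp mode whose
   conditional-expectation predictions explode; when the implied variance
   exceeds twice the observed one, the fit reverts to the kernel estimates
   with a warning.
5. **Scores and prediction.** PACE conditional expectation with model
   quantities linearly interpolated to observation times; a 1e-8 jitter
   stabilizes the inversion at sigma2 = 0. Predictions live on the 100-point
   equispaced grid; values between grid points are linear interpolations; no
   extrapolation outside the domain. New observations update scores only —
   the model is never refit at prediction time.

## Stage-1 classifier

Features are standardized by training mean/SD (zero-variance columns keep
SD 1). The fit maximizes the class-weighted log-likelihood minus
‖β‖²/(2C) with an unpenalized intercept (scikit-learn's L-BFGS at tolerance
1e-12; the objective is the summed-likelihood convention, so uniform row
duplication is equivalent to doubling C). The class weight is exactly
N_slow/N_fast on training labels. The threshold scan covers {0.01, …, 0.99}
and returns the smallest maximizer of fast-class F1 on validation (ties favor
sensitivity). Feature importance is reported both as |β| and as β/SE with SEs
from the weighted, penalty-free observed information at the optimum; a
singular information matrix leaves SEs undefined with a warning.

## Evaluation

Held-out test-set VF values after the baseline window are prediction targets.
Horizons are measured from day 365: bin floor((t−365)/365) for bins 0–5
("Year 0-1" … "Year 5-6"), six or more post-baseline years → "Year >6", plus
a pooled overall row; R² uses the mean of the actuals within each evaluated
set, so the overall row is not an average of per-bin values. Bootstrap CIs
resample *eyes* with replacement (all pairs of a resampled eye enter
together), 1,000 replicates by default, reporting the replicate median and the
2.5/97.5 percentiles; replicates where a statistic is undefined are dropped
and counted. The classification panel reports accuracy, balanced accuracy,
sensitivity, specificity, PPV, NPV, F1, trapezoid AUROC and step-interpolated
AUPRC. Trajectory tables are stratified both by true progressor label
(default) and by the Stage-1 predicted label.

## Pipeline design choices

- Training-time stratification uses measured labels (full-series slopes); at
  inference each test eye is routed by its *predicted* label — the deployment
  scenario. Only baseline-window observations feed score prediction.
- One global seed expands deterministically into per-stage seeds
  (SeedSequence); identical configs produce identical reports up to timings.
- If the validation split contains no fast eyes (possible in very small
  runs), the pipeline warns and defaults the threshold to 0.5 rather than
  aborting; the standalone threshold selector still raises.

## Problem sizes and limitations

The test suite exercises recovery at 500 eyes per stratum (median 4 visits)
and end-to-end runs at 1,000 generated eyes; the acceptance script uses
4,081 eyes for cohort composition, 500 for recovery, and 1,000 for the
pipeline. At 1,000 eyes the fast stratum of the *test split* is tiny (a
handful of eyes), so its long-horizon bins often contain too few prediction
pairs for a defined R² — long-horizon fast-stratum evaluation needs cohorts
several times larger. Known limitations: no covariate-adjusted FPCA, no
confidence bands on predicted trajectories, no derivative estimation, no
robustification of the mean smoother against isolated dense patients, and
eigenvalue floors (a weak second mode can be estimated at zero in very small
strata).
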