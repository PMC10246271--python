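# Methods

`fcmarker` implements a complete analysis chain for case/control
"neuromarkers" built from resting-state functional connectivity (FC)
pooled over imaging sites.  This note records the models, the defaults and
why they were chosen, the numerical decisions, and what the synthetic data
do and do not establish.

## Data model and edge conventions

A connectome on R regions of interest (ROIs) is a vector of the
m = R(R−1)/2 Fisher-z transformed Pearson correlations between ROI time
series, ordered row-major over the strict upper triangle (the order of
`numpy.triu_indices(R, k=1)`).  The full-scale parcellation in this
literature has R = 379 (360 cortical + 19 subcortical), i.e. m = 71,631
edges; all package defaults use a desk-scale R = 50 (m = 1,225) or smaller
so that every analysis, including permutation retraining, runs on one CPU
in minutes.  Participants carry site, diagnosis (0 = control, 1 = patient),
age (years) and sex.  Developmental-stage splits use child: age < 12,
adolescent: 12 < age < 18, adult: age ≥ 18; the child/adolescent bounds
are strict, so subjects aged exactly 12 belong to neither (the convention
for exactly-12 and exactly-18 subjects is not settled in this literature;
we assign 18 to adult and drop 12 from both young splits).

## Time series to edges

The preprocessing chain is nuisance regression → band-pass → scrubbing →
correlation:

1. **Nuisance regression.** Per-ROI OLS residuals on
   [intercept, linear trend, supplied confounds]; the confound table is
   expected to hold motion parameters, tissue signals, their derivatives,
   etc.  A rank-deficient design is refused, naming the collinear columns.
2. **Band-pass.** Second-order Butterworth, 0.008–0.1 Hz, applied
   forward–backward (`filtfilt`), hence zero phase; the testable contract
   is ≤ 1 dB passband loss at 0.05 Hz and ≥ 20 dB attenuation at 0.2 Hz
   for TR = 2 s, not the specific realization.
3. **Scrubbing.** Frames with framewise displacement strictly above
   0.5 mm are censored.  Censoring after filtering avoids feeding the
   recursive filter a discontinuous series.  A floor of 50 surviving
   frames (configurable) guards against meaningless correlations; this
   floor is a package choice, not a literature constant.
4. **Correlation.** Pearson r per unordered ROI pair, clipped to
   |r| ≤ 1 − 1e−7 so the Fisher z = atanh(r) stays finite on degenerate
   (perfectly correlated) pairs.

## Site harmonization (ComBat)

Edge value y_ijv for subject j at site i, edge v, is modelled as
y = α_v + X_j·β_v + γ_iv + δ_iv ε with covariates X = (diagnosis, age,
sex) whose effects must survive the correction.  Estimation is the
standard parametric empirical-Bayes scheme: feature-wise standardization
with site terms constrained to a sample-size-weighted zero sum; normal
priors on γ and inverse-gamma priors on δ² with hyperparameters from the
method of moments across edges; iterated conditional posterior means
(absolute change < 1e−6 or 200 iterations).  The adjusted value is
(σ_v/δ*_iv)(z − γ*_iv) + α_v + X_j·β_v.  The parametric (not the
nonparametric) variant was chosen as the common default; which variant
the upstream literature used is typically unstated.  The implementation
is validated against Bioconductor `sva::ComBat` to ~1e−6 on a fixture.

Operational rules: harmonization is applied to each dataset separately,
never jointly across discovery and validation.  Single-site datasets pass
through unchanged with a warning.  Sites containing only one diagnostic
class are allowed (their site effect is still estimated; the diagnosis
slope is identified by the mixed sites) and warned about, since
patient-free sites occur in real discovery cohorts.

Two properties deserve honesty notes.  First, ComBat is not exactly
idempotent: shrinkage leaves a residual site effect of order
δ²/(n τ²) per pass (~2% RMS at ~150 subjects/site), which a second pass
further reduces; tests assert the geometric decay, not a fictitious exact
fixed point.  Second, in-sample site ANOVAs after ComBat are conservative
by construction (the fitted site means are removed exactly), so
calibration is assessed on held-out subjects adjusted with the fitted
model (`apply_model`), compared against the identical protocol on data
simulated without site effects — both carry the same estimation noise, so
agreement isolates the question "did the correction reach the
null-calibrated level?".

## The marker ensemble

The classifier is an ensemble of k_folds × n_subsamples L1-penalized
logistic regressions (default 10 × 10 = 100):

* **Subsampling.** Each subsample draws a class-balanced random
  undersample of the majority class (without replacement).  This is the
  standard device for the strong control excess in discovery cohorts
  (~3:1); with balanced input it reduces to the identity.
* **Nested CV.** Within a subsample, a stratified outer k-fold split;
  per outer fold an inner 5-fold CV over a 30-point penalty grid,
  log-spaced over three decades below λ_max (the smallest penalty giving
  the all-zero model), selects the λ with minimal mean held-out binomial
  deviance; ties prefer the sparser model.  Features are z-scored per
  edge with outer-training statistics only.
* **Solver.** A glmnet-style coordinate-descent path solver (IRLS outer
  loop, soft-threshold inner loop, active-set sweeps, warm starts along
  the grid), numba-compiled.  The permutation procedures retrain the
  entire ensemble hundreds of times, which rules out per-fit solver
  overheads; correctness is pinned to scikit-learn's liblinear by
  objective-value comparison at matched penalties.  During inner CV the
  grid is walked from the sparse end and stops once the mean held-out
  deviance has not improved for 5 consecutive grid points; deviance
  profiles along the path are effectively unimodal, and under permuted
  labels the optimum sits at the sparse end, so this prunes exactly the
  expensive dense fits the selection would never choose.
* **Diagnostic probability.** The mean of the (up to) 100 logistic
  outputs; a subject is labelled a patient iff it exceeds 0.5 strictly.
  Discovery-set performance always uses out-of-fold probabilities:
  subjects inside a subsample are scored by the classifier of the fold
  that held them out; subjects removed by the undersampling are scored by
  the mean of that subsample's fold classifiers; probabilities are then
  averaged across subsamples.  Resubstitution scores would be optimistic
  and are only used where a test asserts exactly that optimism.

Metrics: confusion counts at the strict 0.5 rule, accuracy, sensitivity,
specificity, Matthews correlation (0 when a marginal is empty), and a
rank-based AUC with ties counted 1/2 — chosen over a trapezoid ROC
integral because it equals the concordance probability exactly, which is
what the oracle tests enumerate.

## Permutation inference

Both significance questions share one engine: labels are shuffled in the
discovery set only, and a full ensemble is retrained per iteration with
the identical configuration (subsample draws and fold splits re-derived
from the iteration seed).

* **Performance.** AUC and MCC of each permuted ensemble are recorded on
  its own permuted out-of-fold probabilities and on every validation set
  with intact labels.  p = (1 + #{null ≥ observed})/(1 + B), never zero.
  Family-wise control across validation datasets uses Holm's step-down,
  applied per metric (whether metrics should be pooled into one family is
  ambiguous in the source literature; per-metric is the conservative
  reading for each metric's family).
* **Edge selection.** The observed statistic per edge is its selection
  count — the number of ensemble classifiers with a nonzero weight on it;
  each permutation contributes the maximum count over all edges.  The
  max-statistic null gives every edge the same reference distribution and
  controls the family-wise error of the selected set.  Counts run over
  all k_folds × n_subsamples classifiers for observed and null alike.
  Significant edges split into hyper-connections (positive mean weight
  over all classifiers, zeros included) and hypo-connections (negative).
* **Budgets.** B is configurable everywhere; 500 is the full-scale
  default, with desk-scale presets of ~50–100 used in tests and the
  acceptance script so a full run stays in minutes.

## Consistency across datasets

Per-edge diagnosis effects are two-sample pooled-variance t-values
(patient − control; Welch available behind a flag; zero-variance edges get
t = 0 and a flag).  Reproducibility checks: (1) Pearson correlation of
t-vectors between datasets, null built by shuffling the second dataset's
labels only (the first vector is the fixed reference), one-sided p;
(2) the count of edges with one strict sign across all datasets (zeros
break consistency); (3) an exact binomial upper tail P(X ≥ x) for x
sign-consistent edges among n marker edges against the connectome-wide
base rate K/M — exact rather than normal-approximate because n is small
in practice (~10²).

## Network enrichment

Every edge belongs to the unordered pair of its ROIs' resting-state
networks (7 cortical networks + "subcortical"; categories partition the
edge set).  Over-representation of hyper- or hypo-connections in a
category uses the hypergeometric tail P = 1 − CDF(x; M, K, n) = P(X > x),
reproducing the printed convention of the source analyses even though the
conventional test is P(X ≥ x); the inclusive tail is available behind a
flag and is never smaller, so the printed form is never anti-conservative.
Bonferroni correction runs over categories × {hyper, hypo}.

## Cross-disorder mapping

A marker applied to another disorder's patients yields a cross-disorder
sensitivity (fraction with mean probability strictly above 0.5), tested
against sensitivities of label-permuted ensembles; the permuted ensembles
are shared with the other permutation tests when run through
`permutation_analysis`, since retraining dominates the cost.  Two markers
define a plane; subjects are placed at their two probabilities and
summarised by quadrant (split at 0.5, boundary values to the low side,
matching the strict labelling rule).  Diagnosis-effect similarity between
disorders is the t-vector correlation restricted to the marker's hyper-
(resp. hypo-) connections.

## The synthetic generator

Every analysis is exercised on synthetic data with planted truth.  Edge
values are baseline_v + diagnosis·d_v·noise_sd + age·β_age,v + sex·β_sex,v
+ γ_sv + δ_sv·ε, with per-site, per-edge additive γ ~ N(0, additive_sd²)
and multiplicative δ ~ U(range) — per-edge rather than per-site scalars,
matching the per-feature site model the harmonization assumes.  Defaults:
R = 50, three sites of 110 controls / 36 patients (≈3:1 imbalance, echoing
discovery cohorts of several hundred controls against ~180 patients),
30 effect edges at |d| = 0.8 with mixed signs, age/sex effects on 10% of
edges, noise_sd = 1, additive_sd = 0.5, δ ∈ (0.8, 1.25).  Validation
datasets share the discovery effect edges with fresh sites and subjects,
per-stage effect attenuation, and a configurable sign-share (the fraction
of effect edges keeping the discovery sign; the flipped count is the
rounded complement, deterministic per dataset, with random positions).
Two-disorder simulations share the control cohort and site effects
exactly and overlap a stated fraction of effect edges with equal signs.
ROI-level simulation produces stationary Gaussian series with a target
correlation plus an FD trace with super-threshold spikes at a stated rate.

What passing tests on these data do *not* show: real FC matrices have
spatially structured covariance between edges, non-Gaussian tails,
site-by-covariate interactions and scanner drift, none of which the
generator emulates; recovery and calibration results here validate the
statistical machinery, not clinical performance.  Published full-scale
classification figures depend on restricted consortium data and are out
of reach of any synthetic benchmark at desk scale.

## Problem sizes and seeds

Tests and the acceptance script choose sizes so each experiment carries
statistical meaning at interactive cost: edge-recovery runs at m = 190
with n = 150/150 and B = 100 permutations; type-I calibration uses 200
replicates of a 40-subject null design with B = 39; the family-wise error
check uses 100 replicates; the cross-disorder asymmetry design uses 10
seeds.  All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`, with per-stage and per-iteration derived
seeds, so any prefix of a permutation stream is reproducible in
isolation.
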