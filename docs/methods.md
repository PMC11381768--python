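# Methods

This note documents the models, conventions and numerical choices behind
`metabopanel`, and what the synthetic studies it ships with do and do not
establish about real data.

## The workflow

The package implements a three-phase plasma-metabolomics diagnostic
workflow:

1. **Discovery.** Untargeted LC-MS feature tables (one per electrospray
   ionization mode) are imputed, corrected for injection-order signal
   drift using pooled QC samples, and mined for a minimal discriminative
   metabolite panel with a linear SVM.
2. **Validation.** The panel metabolites are absolutely quantified by a
   targeted assay with stable-isotope-labelled internal standards
   (SIL-IS), and a concentration-based SVM is trained on one cohort and
   evaluated on held-out and independent cohorts.
3. **Response prediction.** Panel concentrations in a neoadjuvant-
   chemotherapy (NAC) cohort are tested per marker × breast-cancer
   subtype, and the inosine/uridine concentration ratio is evaluated as
   a predictor of pathological complete response (pCR).

## Drift correction

Pooled QC samples — aliquot mixtures of all study samples — are injected
before and after the sequence and after every `qc_every` (default 10)
subject injections. Any trend of a feature's QC intensity over injection
order is instrumental. Per batch and feature, a trend `t_j(order)` is
fitted to the QC points and divided out:

    corrected(i, j) = raw(i, j) · reference_j / t_j(order_i)

with `reference_j` the median QC intensity. Two trend fitters are
provided and selectable by configuration (the upstream convention names
both a LOESS-style and a random-forest-style QC correction without
fixing one):

* `loess_like` (default) — a local-linear lowess smoother through the QC
  points, linearly interpolated between QC orders. Exact on constant and
  linear QC series.
* `ensemble_regression` — the average of 50 bootstrap piecewise-linear
  interpolants over injection order, a randomized-regression ensemble in
  the spirit of random-forest QC correction. Seeded and deterministic.

Numerical conventions: predictions outside the QC order range are
clamped to the nearest QC prediction (no extrapolation, no sign flips at
sequence edges); fewer than 3 QC points in a batch is an error directing
the caller to a global-median fallback; a feature whose trend predicts a
non-positive value anywhere is left uncorrected and flagged. A
correction that does not reduce the feature's QC relative standard
deviation (RSD) is reverted and reported as `corrected: no` — the
contract is that correction never destabilizes QCs. With several
batches, corrected batches are rescaled to the global QC reference
level, removing batch offsets together with drift.

Missing (below-detection) values are imputed *before* correction as 1/10
of the feature's minimum observed peak height across all samples, the
convention of the upstream alignment software's export step.

## Classifier and feature importance

Every sample row is L2-normalized (projected onto the unit sphere); this
uses only the sample's own values, so it is applied once, before any
fold split, and cannot leak across samples. The classifier is the
soft-margin linear SVM

    min_{w,b}  ||w||²/2 + c · Σ_i max(0, 1 − y_i(wᵀx_i + b))

with an unregularized bias, labels +1 = case (BC), −1 = control (NC),
and a decision score of exactly 0 predicting +1. The slack penalty is
`c = 4` on untargeted intensities (discovery) and `c = 5` on absolute
concentrations (validation). libsvm solves exactly this objective; a
quadratic-programming formulation solved independently is the standing
regression oracle (agreement within 1e-6 relative on small instances).

Solver tolerances: 1e-6 for single fits (comfortably inside the oracle
contract) and 1e-3 inside resampling loops, where only the decision rule
matters; an iteration cap guards against rare slow-converging draws.
The convex optimum does not depend on a seed.

Feature importance is the mean of squared weights over all models fitted
during repeated stratified 4-fold cross-validation (2000 iterations by
default for the importance phase). Mean-of-squares rather than
square-of-means makes the estimate robust to sign flips across refits.
Nested top-N models (N = 1…100, 500 CV iterations each by default) trace
accuracy against panel size; the minimal panel is the shortest ranking
prefix whose mean accuracy is within `tolerance` (default 0.01) of the
curve's maximum. A boolean availability mask can remove features that
lack chemical standards or clean MS/MS matches before the prefix is
taken — that filter is a wet-lab input, never computed.

Metric conventions: sensitivity = TP/(TP+FN) with case positive;
specificity = TN/(TN+FP); the 95% CI attached to a mean over CV
iterations is the normal-approximation CI of the mean
(±1.959964·SD/√n_iter), which is why intervals are very narrow at
thousands of iterations; a percentile summary of the iteration
distribution is available behind a flag of the reporting code. Group
comparisons use Welch's unequal-variance t-test by default (Student's
available via `equal_var=True`); families of tests are adjusted by
Benjamini–Hochberg step-up.

## Targeted quantification

The calibrated quantity is the response ratio r = analyte area / SIL-IS
area, which cancels matrix effects and detector gain. Calibration lines
`r = slope·x + intercept` are fitted to 13 calibrator levels by weighted
least squares with weights 1/x² (relative-error weighting — LC-MS noise
scales with signal; exponent 0 recovers OLS, and the closed-form normal
equations are the test oracle at exponents 0, 1 and 2). At least 6
distinct positive levels are required.

Curve acceptance follows bioanalytical convention: each calibrator is
back-calculated through the fitted line; a level passes at |bias| ≤ 15%
(≤ 20% at the lowest, LLOQ-candidate level); the curve is accepted iff
at least 75% of levels pass. LLOQ is the lowest level with ≤ 20% bias
and (when replicate QCs at or below it exist) replicate CV ≤ 20%; LLOD
uses the 3.3·σ/slope convention with σ the response residual scale at
the lowest level — a documented, replaceable constant, since the
original assay's limit values are not available. Concentrations below
LLOQ are flagged but not censored: censoring would silently reshape the
distribution the classifier sees. Calibration is refitted per cohort
file (per analytical batch); a reconstitution dilution multiplier is
provided and defaults to 1 (concentrations reported as measured).

## Synthetic studies

The generators produce the statistical structure the analysis assumes,
so every stage is testable without clinical data.

* **Untargeted cohorts** — lognormal intensities (multiplicative noise,
  drift and fold-changes compose additively on the log scale); planted
  features carry a case/control log2 fold-change split symmetrically
  between arms; a shared per-injection drift factor acts on all features
  through a per-feature sensitivity exponent in [0.5, 1.5] (drift is
  correlated, not identical, across features); pooled QCs are the mean
  of subject true signals, then subjected to the same drift and noise;
  missingness censors each feature's lowest intensities (the
  below-detection mechanism the 1/10-minimum imputation rule assumes),
  not cells at random. Default design: 200 cases / 100 controls, 479
  (ESI+) and 269 (ESI−) features, QC before, after and every 10
  injections, drift amplitude 0.2, noise CV 0.15, 5% missingness.
  Subject acquisition order is randomized so drift is not confounded
  with group.
* **Targeted runs** — per analyte: 13 calibrators on a doubling series,
  4 QC levels (low / low-medium / high-medium / high, 3 replicates),
  and subjects with lognormal true concentrations retained as hidden
  ground truth. The response ratio carries multiplicative noise of CV
  `ratio_cv` (default 5%). Group shifts on the log scale (inosine −0.8,
  uridine −0.6, phenylalanine +0.5, threonine +0.45, at log-SD 0.4,
  nucleosides down and amino acids up in cases) put the four-marker
  classifier in the ~90% accuracy regime reported for such panels.
* **NAC cohorts** — four panel-metabolite concentrations with subtype
  and pCR labels; TNBC group sizes default to 27 pCR / 25 non-pCR.
  Marker log-concentrations share a subject-level factor giving a
  pairwise correlation of 0.5 (plasma metabolite levels co-vary across
  subjects); under that structure a planted standardized difference d
  (pCR shifted down, matching the reported direction for inosine)
  yields the binormal AUC Φ(d/√2) for single markers and for two-marker
  ratios alike, which is the closed form the tests check against.

## What the synthetic tests do and do not show

Passing tests establish that the pipeline's machinery is correct: the
convex fits match independent oracles, the acceptance rules enforce
their boundaries, drift of the planted form is removed, planted effects
of the planted size are recovered, and null data produce null results
at the nominal rates. They do not establish clinical performance: real
plasma data have correlated features, non-lognormal tails, retention-
time-dependent drift, and batch structure richer than a multiplicative
offset, none of which the generators emulate. Reported accuracies on
synthetic cohorts are properties of the chosen effect sizes, not
estimates of diagnostic accuracy in patients.

One limitation surfaced by the synthetic studies is worth stating
plainly: squared-weight importance on per-sample L2-normalized
intensities is abundance-weighted. High-abundance features dominate the
sample norm and the margin geometry, so equally informative features of
much lower abundance rank systematically worse. With the moderate
dynamic range of an identification-filtered feature table
(between-feature baseline log-SD 0.5, the generator default) planted
panels are recovered reliably; when the baseline spread is doubled,
mid- and low-abundance planted features start losing top-10 ranks to
abundant noise features. On data with a wide dynamic range a
scale-equalizing transform (or per-feature standardization) before
weight-based ranking deserves consideration, at the cost of departing
from the published protocol.

## Problem sizes used by tests and the acceptance script

Repeated-CV protocols are exercised at reduced size — 200 importance
iterations and 100 top-N iterations to N = 30 on 500-feature cohorts
(the full protocol defaults of 2000/500/100 remain the pipeline
defaults) — and recovery/null rates are measured over 20 seeds in the
test suite and 8–10 seeds in `scripts/acceptance.py`; quantification
recovery uses 100–200 simulated runs and the NAC ratio analysis 50–100
cohort replicates. These sizes give binomial/CI resolution well inside
the asserted margins.

## Degenerate inputs and tie-breaks

All-zero sample vectors cannot be L2-normalized (error); a class smaller
than the fold count cannot be stratified (error); features missing in
every sample are dropped with a warning; importance ties rank by
ascending feature index; a decision score of exactly zero predicts the
positive class; equal-mean zero-variance groups return t = 0, p = 1;
ratio subjects with non-positive denominators are excluded with a
warning; strata with a single outcome class report NaN AUC/p rather
than failing.
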