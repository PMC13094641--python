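# Methods

`edaki` implements an end-to-end methodology for developing creatinine-based
acute kidney injury (AKI) risk models from emergency department (ED)
encounter data when the outcome — a follow-up serum creatinine (sCr) within
72 h of departure — is missing for most visits. Because real EHR encounter
data cannot be redistributed, every stage is exercised on a synthetic
cohort generator with retained ground truth; the generator's defaults are
calibrated so the synthetic population reproduces the structural features
of a large multi-site ED cohort.

## Outcome definition and staging

AKI is staged from the ratio and absolute rise of sCr over a
patient-specific baseline, per the KDIGO creatinine criteria:

* stage 1: rise ≥ 0.3 mg/dL or ≥ 1.5× baseline;
* stage 2: 2.0–2.9× baseline;
* stage 3: ≥ 3.0× baseline, initiation of renal replacement therapy, or
  sCr reaching ≥ 4.0 mg/dL.

Urine-output criteria are not used. Three deliberate readings of the
criteria, where the consensus text leaves room:

* The ≥ 4.0 mg/dL level counts as stage 3 only when a stage-1 acute-rise
  criterion is also met, following the usual KDIGO convention; otherwise a
  3.8 → 4.0 mg/dL drift in a chronically elevated patient would be staged
  as severe AKI. Because baselines ≥ 4.0 mg/dL are excluded from the
  cohort anyway, this divergence is rare.
* Ratio bands are half-open: stage 2 is [2.0, 3.0), the stage-3 ratio
  criterion is ≥ 3.0.
* The 180-day baseline lookback and the 72-h outcome window are closed at
  both endpoints (boundary measurements count).

Baseline sCr is the median of all measurements in the 180 days before
arrival; a sole measurement is used as-is; with no history the baseline is
back-calculated by inverting the 2021 race-free CKD-EPI creatinine
equation at a reference eGFR of 75 mL/min/1.73 m² (the conventional
back-estimation target; configurable). The forward equation is a strictly
decreasing piecewise power law in sCr, so the inversion is closed-form and
round-trips to better than 1e-6 relative error. An even-length history
uses the standard midpoint median.

The per-visit outcome is *new or progressive AKI*: the peak stage within
72 h of departure exceeds the arrival stage (computed from the first in-ED
sCr against the same baseline). A second target flags progression reaching
stage ≥ 2; any progression that lands at stage 2 or 3 counts, whether from
stage 0 or stage 1. Visits with no follow-up sCr and no RRT are flagged
outcome-missing. Study exclusions: end-stage kidney disease / RRT
dependence, baseline ≥ 4.0 mg/dL, or stage 3 already present on arrival.

## Missing-outcome strategies

Four training-set constructions are compared on identical cohorts:

1. **Complete case** — outcome-observed visits only, unit weights.
2. **Assume negative** — all visits; missing outcomes coded negative.
3. **Multiple imputation** — a preliminary model fit on complete cases
   predicts an outcome probability for each incomplete visit; each such
   visit contributes m = 20 replicate rows with independent Bernoulli
   draws at weight 1/m, so every encounter carries total weight 1
   ("equal representation"). A single pooled model is fit; no Rubin
   variance pooling, since only point predictions are consumed.
4. **Inverse probability weighting (IPW)** — complete cases weighted by
   1/P(observed | covariates). The observation propensity is a
   gradient-boosted model fit on the full cohort with the same predictor
   schema as the risk models (the clinical factors that drive repeat
   testing — age, kidney history, arrival stage, vitals, labs — are all
   predictors, which is what makes the missing-at-random assumption
   plausible). Propensities are clipped below at 0.01, bounding weights at
   100. Weights for the fitting cohort use 5-fold cross-fitted (out-of-fold)
   propensity predictions: in-sample predictions are optimistically pulled
   toward the training labels, which deflates the weights enough to break
   the Horvitz–Thompson identity (the weight sum over observed visits
   should approximate the cohort size).

## Risk models

Both targets are fit with gradient-boosted trees (XGBoost). Missing
continuous predictors stay NaN and are handled by the learner's
sparsity-aware split finding; missing categorical predictors become an
explicit "null" level. Hyperparameters are selected by weighted log-loss
on an inner 3-fold split over a grid (max_depth {3, 5}, n_estimators
{100, 300}, learning rate {0.05, 0.1}, subsample 0.8, one L2 value); the
grid is caller-overridable and a single-point grid skips the search. The
pipeline's default operating point is max_depth 3, 150 rounds, learning
rate 0.1: at synthetic scale, longer boosting overfits the observed
stratum and visibly biases the full-cohort mean prediction downward.
Sample weights are normalized to mean 1 before fitting so that the tree
regularization terms — which are absolute — leave predictions invariant to
the overall weight scale.

Evaluation uses two independent designs: 10-fold cross-validation with
folds grouped by patient (deterministic hash of patient id, so fold
assignment is order-invariant and repeat visits never straddle
train/test), and a temporal split (development era before 2023, validation
after). Strategy construction — propensity fitting, imputation — is re-run
inside each training fold to avoid leakage, and test folds contain only
outcome-observed visits.

## Performance assessment

Discrimination and calibration on outcome-observed visits: ROC AUC with
DeLong structural-components confidence intervals and paired tests (ties
get half credit throughout; the implementation is checked against
brute-force pair counting), precision-recall with step-interpolated area
(linear interpolation is optimistic), equal-frequency decile calibration,
and the Brier score.

The second assessment covers the *whole* cohort: per strategy, the mean
predicted probability in the outcome-observed and outcome-missing strata
is compared against the observed outcome rate and, for the missing
stratum, an expected rate equal to 0.36 × the observed-stratum rate. The
0.36 ratio is the published relative frequency of short-term kidney
outcomes after ED discharge vs hospitalization in the same population;
most outcome-missing visits are discharges. Confidence intervals on mean
predictions use the normal approximation (mean ± 1.96·SD/√n).

## MNAR sensitivity analysis

Inverse-probability weighting assumes outcomes are missing at random given
covariates. The sensitivity analysis, following the
Rotnitzky–Faraggi–Schisterman approach, posits instead that the
observation log-odds are f(X) + μ·Y: patients who develop AKI are e^μ
times more (μ > 0) or less (μ < 0) likely to have a follow-up sCr, beyond
what covariates explain. For each μ on a grid (default −1 to 3 in steps of
0.5), f(X) is taken from the fitted propensity model's margin, a scalar
intercept is recalibrated so the implied inverse-probability weights over
observed visits sum exactly to the cohort size (a Horvitz–Thompson
self-consistency condition, solved by bracketed root finding; only the
intercept is recalibrated, not f jointly — a stability and speed choice),
and the AUC is recomputed as the weighted Mann–Whitney statistic over
observed positive/negative pairs. At μ = 0 this reduces to the
missing-at-random IPW AUC; with no missing outcomes the weights are all 1
and the plain AUC is returned at every μ. Bootstrap resampling of whole
visits (observed and missing alike, default 1000 resamples, percentile
intervals) gives CIs and paired contrasts against the complete-case
reference model, with the intercept recalibrated inside every resample.

An important usage constraint, visible in the recovery experiments below:
the tilt estimator corrects *selection* bias, not *overfitting* bias. If a
model is scored on its own training visits, the inflated observed-stratum
AUC swamps the selection effect and tilting moves the estimate the wrong
way. All sensitivity analyses here therefore use out-of-sample predictions
(the temporal validation era).

## The synthetic cohort generator

One row per ED encounter: age, sex, five sites, six chief-complaint
categories, two triage vitals (SBP, HR), four labs (BUN, sodium,
potassium, hemoglobin), three comorbidity flags (CKD, diabetes, CHF) plus
a rare ESKD flag, disposition, timestamps spanning 2017–2024 with 78.5% of
visits before the 2023 temporal cutoff, a creatinine history, the first
in-ED sCr, and a follow-up series. This compact covariate set stands in
for the hundreds of predictors a production model would use; the
methodology, not the feature inventory, is what the package tests.

The generating model is fully explicit:

* A latent outcome Y ~ Bernoulli(logistic(β·X)); conditional on Y = 1, a
  latent peak stage drawn from a severity allocation, renormalized over
  stages exceeding the arrival stage (drawn 91.5 / 7.1 / 1.4% across
  stages 0–2).
* Observation (follow-up measured) ~ Bernoulli(logistic(α·X + μ_true·Y)).
  μ_true = 0 is the missing-at-random case — observation is conditionally
  independent of Y given covariates by construction, which a stratified
  permutation test on propensity quantiles verifies. α shares covariates
  with β, so the observed stratum is risk-enriched, as in real EDs.
* The first in-ED sCr is the true baseline times a ratio drawn inside the
  arrival-stage band; follow-up sCr is the true baseline times a
  stage-band multiplier (1.65–1.95 / 2.15–2.80 / 3.10–4.00) with small
  lognormal noise (sd 0.02), so the labeler recovers the latent stage up
  to baseline-estimation noise; negatives never exceed their first in-ED
  value. About 10% of latent stage-3 outcomes also receive RRT.
* Creatinine history: half of visits carry no prior measurements
  (exercising the CKD-EPI imputation path on every run); historical values
  scatter around the true baseline with lognormal sd 0.07. Patients
  without history draw their true baseline near the CKD-EPI value at eGFR
  75 (lognormal sd 0.10) — the clinical rationale for back-calculation is
  precisely that such patients usually have unremarkable kidney function —
  and diagnosed CKD/ESKD patients always carry history, since the
  diagnosis implies a measured creatinine. Without this coupling the
  imputation error doubles the labeled severe-AKI rate.
* Continuous predictors go missing completely at random at 10%.

Intercepts and the severity allocation were calibrated once, by
simulation, to the published cohort structure — ~34.5% of visits with a
follow-up sCr, 5.70% any / 1.62% severe AKI among observed visits, ~40%
hospitalized — and then frozen (measured at n = 60,000: 34.4%, 5.71%,
1.67%). All randomness flows from one seed through deterministically
spawned sub-streams, so identical configurations reproduce cohorts
bit-for-bit.

What the generator does *not* emulate: inter-visit correlation beyond a
shared patient id (each encounter is treated as an independent index
visit), temporal drift between eras, site-level heterogeneity in outcome
rates, informative predictor missingness, and the long tail of real
predictor inventories. Passing tests therefore demonstrate that the
estimators recover truth under the stated generating model, not that any
particular AUC value transfers to real EHR data.

## Problem sizes and numerical choices

The recovery experiments run at n = 20,000 visits per cohort (10 seeds for
the missing-at-random recovery study, 5 cohorts × 40 bootstrap resamples =
200 replicates for the MNAR study) and the reported cohort structure at
n = 50,000 — sizes chosen so a full verification pass completes in minutes
on one CPU while leaving Monte-Carlo error well below the effects being
measured. Root finding for the intercept recalibration brackets c in
[−30, 30] with 1e-10 tolerance; propensity clipping at 0.01; model
probabilities clipped to (1e-12, 1−1e-12); degenerate inputs
(single-class training data, all-observed or all-missing cohorts, empty
strata) raise informative errors rather than returning silent defaults.

## Known limitations

* The IPW estimand is the full-cohort rate of the *labeled* outcome; the
  labeler itself has a small irreducible error against the latent truth
  (~2% relative on the any-AKI flag), dominated by baseline estimation.
* The MNAR tilt uses the MAR-fitted propensity margin as f(X); under
  strong true MNAR this f absorbs part of the outcome effect through its
  covariate correlation, slightly attenuating the tilt. The recovery
  experiment shows the residual error is an order of magnitude smaller
  than ignoring the MNAR mechanism.
* Multiple imputation draws all m replicates from one preliminary model
  fit; between-imputation model uncertainty is not propagated.
* The pipeline's reported metrics use the temporal split; full 10-fold
  cross-validation is available as a library call
  (`edaki.training.cross_validate`) but is not run for all strategy ×
  target pairs inside every pipeline invocation.
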