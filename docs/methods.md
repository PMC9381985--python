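# Methods

This note documents the scientific and numerical choices behind `fhrisk`:
what each stage computes, the defaults and why, what the synthetic cohort
generator does and does not emulate, and the known limitations.

## Patient record and derived quantities

The unit of analysis is one adult (≥ 18 y) first-ever ASCVD admission.
Lipids are mmol/L (Lp(a) mg/L); `ldl_c` and `tc` are the admission maxima
and are required — rows missing either, or under-age rows, are excluded
and counted per reason. Optional fields (Lp(a), family history, onset
ages) are "absent", never imputed; diagnostic criteria treat absent data
as "item not met".

**Premature-event flags.** Two sex-specific cutoff conventions coexist:
DLCN (men < 55 y, women < 60 y) and Taiwan (men < 45 y, women < 55 y).
Onset equal to the cutoff is *not* premature (strict `<`). Family-history
flags use the relative's sex and onset age; an onset recorded without the
relative's sex yields an absent flag plus a warning. Premature stroke and
peripheral-vascular-disease cutoffs are not fixed by any of the shipped
criteria's source documents; they default to the DLCN cutoffs (these flags
feed DLCN-family point items) and are configurable.

**Untreated LDL-C.** Criteria were developed on therapy-naive lipids, so
observed LDL-C is back-corrected by the expected proportional reduction of
the therapy potency class: `ldl_untreated = ldl_c / (1 − r)` with defaults
r = {none 0, low 0.20, medium 0.35, high 0.50}. These fractions are
round-number summaries of typical statin-potency effects; they are plain
config values, overridable per run and recorded in every report. Therapy
duration is accepted in the schema but enters no computation.

## Criterion engine

Definitions are data, not code: every cutoff, point value and level band
lives in a YAML file, so a corrected item table drops in without a
release. Points mode sums fired items (within a `group`, e.g. the LDL
bands or the family-history pair, only the highest-scoring firing item
counts) and bands the total into ordered levels; rules mode awards the
highest level whose boolean combinator (`all_of` / `any_of` / `any_k`)
over named items is satisfied, with the lowest level as default. Ties
between levels are impossible by construction.

The DLCN file encodes the published adult point table (family history 1–2,
premature CHD 2, premature cerebral/peripheral disease 1, tendon
xanthomata 6, arcus before 45 y 4, LDL bands ≥ 8.5 → 8, 6.5–8.4 → 5,
5.0–6.4 → 3, 4.0–4.9 → 1, DNA 8; levels < 3 / 3–5 / 6–8 / > 8). The
mainland-China modification (mDLCN) keeps the structure with the 8-point
LDL band starting at 6.0 mmol/L and "possible" reachable from 3.5; the
Taiwan criteria (TW) keep the DLCN bands but use the stricter premature
ages. The remaining eight definitions encode their published sources
adapted to this record schema; where a source leaves a value unstated
(e.g. the Lp(a) threshold in the Lp(a)-augmented DLCN, set to 500 mg/L),
the file comments say so and the value is editable in place. Genetic-test
items are present in the five criteria that include them but the test
defaults to `not_done`, so e.g. the shipped JFHMC — which requires genetic
confirmation — flags nobody in an untested cohort.

Binarization for head-to-head comparison: 3- and 4-level criteria collapse
their top two levels into "risky", 2-level criteria their top one; the
reference uses top-2. The HYR voting stage instead groups everything above
"unlikely" (top-3) as high risk.

## Tool assessment

Each tool's risky flags are cross-tabulated against the reference flags
into exact 2×2 counts. For a hard binary decision the ROC curve has one
interior vertex, so its area equals the balanced accuracy (Sen + Spe)/2 —
the AUC convention used for this table (graded-score rank AUC lives in the
model stage). Undefined ratios (zero denominators) are reported as absent,
never as 0. Internal values keep full precision; percentages round
half-up to 2 decimals only at report time. Candidate selection excludes
tools flagging zero patients, then takes the sensitivity maximum (ties:
higher specificity, then AUC, then declaration order) and the specificity
maximum (ties: higher sensitivity, then AUC); the two picks must differ.

## Hybridization (HYR)

The reference plus the two picks — three 4-level verdicts on the same
scale — combine by **ordinal median** (the sorted middle vote). The median
equals the majority label whenever two voters agree, and the binary
outcome "median ≥ possible" is identical to "at least 2 of 3 votes above
unlikely". The combining rule is a pluggable callable so an explicit
64-row combination table can replace the median verbatim. Weighted voting
and voter counts other than three are out of scope.

## Variable selection

Univariate screen: continuous variables use Welch's t-test when both
groups pass a Shapiro normality check (on a subsample capped at 500,
α = 0.05), otherwise Kruskal–Wallis; categorical variables use χ², with
Fisher's exact fallback when ≥ 20% of expected counts are below 5 (2×2
only). P-values are two-sided and uncorrected (the screen is descriptive,
not confirmatory).

Four selection methods vote: (1) forward/backward stepwise logistic
regression on likelihood-ratio tests with entry p 0.1 / stay p 0.2 — LRTs
rather than Wald statistics because Wald collapses under complete
separation, where a ridge-regularized refit backs up the MLE; odds ratios
are reported from the final model. (2) Random-forest Gini importance,
keeping variables above the largest gap in the sorted importances
(threshold overridable). (3)–(4) Lasso and elastic-net (mixing 0.5)
logistic paths on standardized features, with the penalty chosen by
10-fold cross-validated log-loss under the one-standard-error rule; the SE
follows the glmnet convention (spread of per-observation out-of-fold
losses), which prunes decisively harder than a fold-mean SE and matches
`cv.glmnet`'s `lambda.1se` behaviour on identical data. Nonzero
coefficient ⇒ selected.

Consensus keeps variables selected by ≥ 3 of the 4 methods (configurable),
plus an explicit force list minus a drop list — the formalization of any
manual curation, recorded in the report for auditability. The shipped
nine-variable preset (`PRESET_NINE`: untreated-era LDL-C, pCHDTW,
pCHD_fhTW, pStroke_fh, pStroke, pPVD, tendon xanthomata, age, therapy
level) is the default model feature set.

## Risk models

Nine methods share one harness. Defaults: XGBoost 200 trees / depth 4 /
learning rate 0.1; RF 300 trees with `min_samples_leaf` 20 and balanced
class weights; SVM with RBF kernel, γ = 0.01 on standardized features and
balanced class weights; BPANN = one hidden layer of 2·features + 1
logistic units with early stopping; logistic regression with balanced
class weights. The AdaBoost variants wrap SVM / BPANN / LOG in a
**resampling** AdaBoost (each round fits a fresh base learner on a
bootstrap drawn from the current weight distribution), so base learners
need no native sample-weight support. The stacking ensemble feeds
out-of-fold (5-fold) base scores to a logistic meta-learner whose weights
are constrained nonnegative — base scores are all positively oriented, so
negative stacking weights only fit noise, and the constraint keeps the
ensemble monotone in every base score.

Two smoothness choices are deliberate and doubly motivated: the large RF
leaves and small SVM γ regularize high-variance surfaces, and together
with a monotonicity constraint on the tree learners for untreated LDL-C
(`monotonic_cst`; a clinical prior — FH risk never falls as LDL-C rises)
they keep the fitted risk surface non-decreasing along the lipid axis,
which is what the PDP interpretation stage reads off.

**Evaluation scheme.** Patients are assigned to 10 label-stratified folds;
each repeat trains on 7 seeded-randomly chosen folds and tests on the
remaining 3. The repeat count defaults to 10 and is a plain analysis
parameter (the shipped test and acceptance runs use 2–3 repeats; means
stabilize quickly at n = 5,000). Within the training folds a stratified
quarter is held out: the model fits on the other three quarters and an
isotonic (pool-adjacent-violators) map from raw score to probability fits
on the holdout, clamping outside the fitted range. Probability metrics are
reported for both calibrated and raw probabilities (margin scores read as
probabilities are exactly what calibration repairs — uncalibrated SVM/RF
rank well but score near-uselessly as probabilities). Metric identities
asserted in tests: BS_all = prevalence·BS_1 + (1−prevalence)·BS_0 and
RMSE_prob² = BS_all. Calibration error is the mean absolute gap between
predicted and observed rates over 10 equal-frequency bins (bin rule
configurable). Class imbalance (≈ 1:4 and steeper) is handled by
stratification and class weights, never by resampling evaluation data.

## Interpretation

ICE fixes one feature at each of 50 equally spaced grid points between the
1st and 99th percentile of its observed values (grid configurable) and
predicts with everything else untouched; PDP is the pointwise mean of the
ICE curves, on the probability scale. Therapy-stratified PDPs recompute
the curve within each potency stratum (optionally on a seeded patient
subsample — the standard cost control; predictions, not fits, so no
statistical leakage). `threshold_summary` reports grid-resolution
intervals where a PDP exceeds a probability cutoff — never interpolated
"exact" thresholds, since the PDP is itself an average of model
evaluations. PDP shapes are descriptive: patients are substituted into
other patients' covariate patterns, so confounded correlations pass
through untouched and no causal reading is intended.

## Synthetic cohort generator

The generator emulates the marginal structure of a large single-center
first-ever ASCVD admission cohort: n = 5,597; 71.34% male; age
63.02 ± 11.44 y; observed LDL-C ≈ 2.4 mmol/L; Lp(a) log-normal matched to
mean 177.79 / SD 215.07 mg/L; tendon xanthomata ≈ 0.1%; therapy mix
1,947 / 312 / 3,210 / 128 (none/low/medium/high). Structure: a
two-component mixture —

* **background** (weight 0.95), calibrated to the DLCN-unlikely stratum
  of such a cohort: observed LDL-C 2.23 ± 0.70, premature CHD 19%, no
  tendon xanthomata or premature arcus, untreated LDL-C bounded at
  6.4 mmol/L. The background age mean (63.7) is solved from the overall
  target given the FH-like component; untreated-LDL means are observed
  means divided by the therapy-mix average retention E[1 − r] ≈ 0.78.
* **FH-like** (weight 0.05): untreated LDL-C 4.8 ± 1.5 mmol/L, age mean
  50 y, premature CHD probability 0.95, tendon xanthomata 2%, family
  history odds × 8.

LDL-C is drawn on the untreated scale and attenuated by the drawn
therapy's reduction fraction, so downstream back-correction recovers the
component bounds exactly. Consequently no background record can exceed 8
DLCN points: every DLCN-definite case comes from the FH-like component —
a designed, testable property. Event-onset ages are drawn uniformly below
(premature) or above (non-premature) the sex-specific cutoff, truncated
at the current age; TC is LDL + HDL + a positive remainder, enforcing
TC ≥ LDL + HDL.

What the generator does **not** emulate: within-component correlations
(LDL × age, smoking × CHD), measurement error, longitudinal therapy
changes, genetic test results (always `not_done`), or the real cohort's
exact risk-group proportions. Passing tests on synthetic data therefore
demonstrate pipeline correctness and qualitative behaviour (the
sensitivity/specificity ordering of mDLCN vs TW, the LDL-driven risk
gradient), not clinical performance numbers — real-cohort metrics such as
model AUCs are *not* reproducible without the original data, and the test
suite asserts properties (e.g. stacking AUC ≥ 0.90 and at least best-base
− 0.01 at n = 5,000) rather than published point values.

## Numerical details and degenerate inputs

* Percent rounding is half-up, applied only at report time.
* Zero-denominator metrics are `None`; single-class test folds get no rank
  AUC; empty outcome classes get no class-wise Brier score.
* Constant calibration scores yield a constant (prevalence) map plus a
  warning; constant variables get no univariate p-value plus a warning.
* All estimators run single-threaded with seeds derived from the run seed;
  the whole pipeline is byte-reproducible from config + seed (reports
  embed a config digest and carry no timestamps).
* AdaBoost rounds whose resample is single-class are skipped; a round with
  weighted error ≥ 0.5 resets the weights; if no round survives, a single
  unweighted base fit stands in.

## Known limitations

* The 11 criterion files are adaptations to this record schema; items a
  source defines on unavailable fields (e.g. children's LDL percentiles)
  are approximated by the nearest available proxy, and several unstated
  cutoffs are explicit config defaults. They are faithful in structure,
  editable by design, and not a clinical implementation.
* The ordinal-median voting rule reproduces the intended binary behaviour
  and both documented 4-level examples, but other 4-level mappings exist;
  the rule is pluggable.
* Balanced-accuracy AUC applies to hard decisions only; comparing it with
  graded-score rank AUCs across stages is a category error.
* Pediatric variants, homozygous-FH-specific scoring, EMR ingestion and
  genetic confirmatory testing are out of scope.
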