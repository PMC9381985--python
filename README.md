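# fhrisk

Hybrid familial-hypercholesterolemia (FH) risk assessment for ASCVD
cohorts: a declarative engine for 11 clinical FH diagnostic criteria, a
head-to-head assessment harness, majority-vote hybridization, and
calibrated machine-learning risk models with ICE/PDP interpretation.

## The problem

FH is an autosomal-dominant disorder of LDL metabolism that causes
premature arteriosclerotic cardiovascular disease (ASCVD), and it is
heavily underdiagnosed: the established phenotypic scores — the Dutch
Lipid Clinic Network criteria (DLCN), Simon Broome Register, MEDPED and
their regional modifications — trade sensitivity against specificity
differently in different populations, and no single cutoff set works
everywhere. `fhrisk` implements a hybrid strategy for first-ever ASCVD
admission cohorts:

1. **Score** every patient under 11 criteria (SBR, DLCN, MEDPED, JFHMC,
   LDL-C/TC, AHA, SCCFH, Lp(a)+DLCN, mDLCN, TW, CHC), shipped as editable
   YAML definitions over a harmonized patient record. Scoring uses the
   estimated *untreated* LDL-C, back-corrected from the therapy potency:
   `LDL_untreated = LDL_observed / (1 − r)`.
2. **Assess** each tool against a reference criterion (default DLCN,
   binarized over its top two levels) with the five-metric block
   Sen / Spe / PPV / NPV / AUC, where for a hard binary decision
   AUC = (Sen + Spe)/2 (balanced accuracy). The sensitivity champion and
   the specificity champion are selected; tools flagging nobody are
   excluded.
3. **Hybridize** the reference and the two champions by ordinal-median
   voting into the 4-level HYR label; HYR is high-risk exactly when at
   least two of the three votes are above "unlikely".
4. **Select** model features by a univariate screen plus a four-method
   consensus (stepwise logistic with entry/stay p = 0.1/0.2, random-forest
   Gini importance, lasso and elastic-net at the cross-validated
   one-standard-error penalty): keep variables chosen by ≥ 3 of 4 methods.
5. **Model** the binary HYR with nine methods — XGBoost, RF, RBF-SVM,
   a one-hidden-layer back-propagation network (BPANN), logistic
   regression, resampling-AdaBoost wrappers of the last three, and a
   stacking ensemble (RF+SVM+BPANN+LOG bases, logistic meta-learner) —
   under a 10-fold stratified scheme where each repeat trains on 7 random
   folds and tests on the other 3. Raw scores are recalibrated by isotonic
   regression, and both classifier metrics (accuracy, sensitivity, F,
   G-mean, rank AUC, RMSE) and probability metrics (rank AUC, RMSE,
   calibration error, Brier scores per class and overall) are reported as
   mean ± SD over repeats.
6. **Interpret** the fitted model with individual-conditional-expectation
   (ICE) curves and partial-dependence plots (PDPs), stratified by
   lipid-lowering-therapy potency, plus grid-resolution threshold regions
   (e.g. the lowest LDL-C at which the predicted risk exceeds 0.5).

Because no patient-level data ship with the package, a seeded synthetic
cohort generator (`fhrisk.simulate`) emulates a realistic first-ever
ASCVD admission cohort (n = 5,597, 71.3% male, age 63 ± 11 y, observed
LDL-C ≈ 2.4 mmol/L, rare tendon xanthomata) as a background + FH-like
two-component mixture, so the whole pipeline is testable end to end.

## Worked example

```bash
fhrisk simulate --n 5597 --seed 1 --out run/
fhrisk score --out run/
fhrisk assess --out run/
fhrisk hybridize --out run/
```

which prints

```
wrote 5597 patients to run/cohort.csv
scored 5597 patients under 11 criteria
sensitivity pick: MDLCN, specificity pick: TW, excluded: ['JFHMC']
HYR high-risk patients: 466
```

Reading: against the DLCN reference, the mainland-China-modified DLCN
(mDLCN, lower LDL bands) is the most sensitive candidate tool and the
Taiwan criteria (TW, stricter premature-age cutoffs) the most specific;
JFHMC is excluded because without genetic testing it flags no one. The
median vote of DLCN/mDLCN/TW labels 466 of 5,597 synthetic patients
(8.3%) high-risk. `run/assessment.csv` holds the per-tool metric table;
`fhrisk select`, `fhrisk train` and `fhrisk interpret` continue the
pipeline (consensus features, the model report JSON, and tidy PDP curve
exports). The same steps are available as library calls (see
`fhrisk.pipeline`).

The library also reproduces published tool-comparison arithmetic exactly:
feeding a 2×2 of (tp 140, fp 387, fn 4, tn 5066) into
`fhrisk.performance` yields Sen 97.22%, Spe 92.90%, PPV 26.57%,
NPV 99.92%, AUC 95.06%.

## Layout

- `src/fhrisk/cohort.py` — patient record, premature-event flags, untreated LDL
- `src/fhrisk/criteria.py` + `src/fhrisk/data/criteria/*.yaml` — the criterion engine and 11 definitions
- `src/fhrisk/assessment.py` — 2×2s, the five-metric block, candidate selection
- `src/fhrisk/hybrid.py` — ordinal-median voting (HYR)
- `src/fhrisk/selection.py` — univariate screen + four-method consensus
- `src/fhrisk/models.py` — the nine methods, split plans, isotonic calibration, metrics
- `src/fhrisk/interpret.py` — ICE/PDP, stratified PDPs, threshold regions
- `src/fhrisk/simulate.py` — the synthetic ASCVD cohort generator
- `src/fhrisk/cli.py`, `src/fhrisk/pipeline.py` — orchestration
- `docs/methods.md` — the methods note (model assumptions, defaults, limitations)
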