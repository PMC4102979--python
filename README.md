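# romadx

Preoperative triage of adnexal masses with serum biomarkers: a reusable
implementation of ROMA (Risk of Ovarian Malignancy Algorithm) scoring and
the complete diagnostic-performance evaluation that goes with it.

## The problem

A woman scheduled for surgery for an ovarian / adnexal mass should be
referred to a gynecologic-oncology centre if the mass is likely malignant.
Serum CA125 (U/mL) and HE4 (pmol/L) are the standard biomarkers for this
triage. ROMA combines them through a menopause-specific predictive index

```
pre-menopause:   PI = -12.0 + 2.38·ln(HE4) + 0.0626·ln(CA125)
post-menopause:  PI = -8.09 + 1.04·ln(HE4) + 0.732·ln(CA125)

ROMA(%) = 100 · e^PI / (1 + e^PI)
```

and the question a validation study asks is: at the best cutoff, how well do
CA125, HE4 and ROMA separate benign masses from epithelial ovarian cancer
(EOC), overall and within pre-/post-menopausal and early/advanced FIGO-stage
subgroups?

`romadx` provides, as a library with a thin CLI:

- **`romadx.cohort`** — the patient-level data model, validated CSV I/O, and
  the stratification rules (total, pre/post-menopause, early/advanced stage
  with all benign controls retained);
- **`romadx.score`** — ROMA scoring (numerically stable logistic transform);
- **`romadx.diagnostics`** — confusion tables at a cutoff (score ≥ cutoff is
  positive) and the full metric suite: sensitivity, specificity, PPV, NPV,
  diagnostic accuracy (Wilson score 95% CIs), LR+/LR− (log-method CIs),
  diagnostic odds ratio, Cohen's kappa;
- **`romadx.roc`** — empirical ROC curves, Mann–Whitney AUC with
  Hanley–McNeil or DeLong CIs, Youden-optimal cutoffs over inter-score
  midpoints, paired DeLong AUC comparison with a seeded bootstrap CI;
- **`romadx.baseline`** — Mann–Whitney / chi-square / Fisher-exact baseline
  group comparisons;
- **`romadx.simulate`** — a synthetic-cohort generator whose marker
  distributions are calibrated (truncated log-normals, matched medians) to
  the group-level summaries of a published 99-patient case series, so the
  whole pipeline is testable without patient data;
- **`romadx.pipeline`** — the end-to-end driver writing a deterministic
  report bundle (unrounded JSON + presentation TSVs + run log).

## Worked example

```python
>>> from romadx import roma_from_markers
>>> roma_from_markers(he4=56.0, ca125=29.0, status="pre")
RomaResult(pi=-2.20887025709319, roma_percent=9.895676030650678)
```

A pre-menopausal patient at the cohort-median markers (HE4 56 pmol/L, CA125
29 U/mL) has PI = −2.209, i.e. ROMA ≈ 9.9% — below the total-cohort
decision cutoff of 18.3%, so she would be triaged as low risk. The same
markers score 19.2% post-menopausally: ROMA deliberately treats marker
elevations as more alarming after menopause.

Evaluating a marker against pathology (`python examples/02_confusion_metrics.py`):

```
confusion table at ROMA >= 18.3%:  TP=32 FP=2 FN=11 TN=54
         sensitivity:   74.419  (95% CI 59.762 - 85.070)  [wilson]
         specificity:   96.429  (95% CI 87.881 - 99.015)  [wilson]
                 ppv:   94.118  (95% CI 80.906 - 98.372)  [wilson]
                 npv:   83.077  (95% CI 72.184 - 90.279)  [wilson]
 diagnostic_accuracy:   86.869  (95% CI 78.820 - 92.163)  [wilson]
         lr_positive:   20.837  (95% CI 5.283 - 82.180)  [log-method]
         lr_negative:    0.265  (95% CI 0.159 - 0.443)  [log-method]
     diagnostic_odds:   78.545  (95% CI 16.361 - 377.088)  [log-method]
        cohens_kappa:    0.726  (95% CI 0.587 - 0.865)  [asymptotic-normal]
```

Reading: of 43 EOC cases, ROMA at the ≥ 18.3% cutoff caught 32
(sensitivity 74.4%), with only 2 of 56 benign masses misflagged
(specificity 96.4%); a positive ROMA multiplies the odds of malignancy
about 21-fold.

The other scripts in `examples/` walk through ROC/Youden analysis, cohort
simulation, baseline comparisons, and the full stratified report bundle.
The CLI mirrors them:

```bash
romadx simulate --seed 1 --out cohort.csv
romadx score cohort.csv --out scored.csv
romadx evaluate cohort.csv --marker roma --youden
romadx roc cohort.csv --marker roma --compare ca125 --seed 1
romadx report --config config.yaml
```

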