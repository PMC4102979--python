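# Methods

## Scope and model

`romadx` evaluates serum CA125, HE4 and the combined ROMA index as
preoperative classifiers of adnexal-mass pathology (benign vs epithelial
ovarian cancer). ROMA is a fixed, externally derived logistic score: the
menopause-specific predictive index PI is linear in ln(HE4) and ln(CA125)
(coefficients −12.0, 2.38, 0.0626 pre-menopause; −8.09, 1.04, 0.732
post-menopause) and ROMA(%) is its logistic transform times 100. The
package does not refit these coefficients; they are treated as part of the
test definition, applied to raw assay outputs with no unit conversion
(CA125 in U/mL, HE4 in pmol/L — the standard unit for the HE4 EIA; the
package assumes inputs are already on these scales).

A classification is positive when the score is at or above the cutoff
(closed on the positive side). Stage-stratified evaluation follows the
case–control convention: the early-stage stratum is FIGO 1–2 cases plus
*all* benign controls, the advanced-stage stratum FIGO 3–4 cases plus all
benign controls, so the two strata share the control series.

## Metrics and confidence intervals

All proportion metrics (sensitivity, specificity, PPV, NPV, diagnostic
accuracy) are percentages with Wilson score 95% intervals (z = 1.959964),
i.e. the inversion of the normal score test; the lower bound is exactly 0
at x = 0 and the upper exactly 100 at x = n. Wilson was chosen because it
behaves sensibly at the small, extreme counts this design produces (9/9
specificities post-menopause) and is the interval that reproduces published
clinical reporting of this kind.

Likelihood ratios are computed on unrounded proportions with log-method
(Simel-type) CIs, SE(ln LR+) = sqrt((1−sens)/TP + spec/FP). The diagnostic
odds ratio uses the log CI with SE = sqrt(1/TP + 1/FP + 1/FN + 1/TN); an
optional Haldane 0.5 correction handles empty cells when explicitly
requested, otherwise an empty error cell yields a tagged infinite DOR.
Cohen's unweighted kappa uses the asymptotic normal CI
kappa ± 1.96·sqrt(po(1−po)/(n(1−pe)²)). Any metric with an empty
denominator returns a tagged undefined estimate rather than raising, so
batch stratified runs always complete.

## ROC, AUC and cutoff optimisation

The ROC curve is the empirical step polygon with one vertex per distinct
observed score plus the two trivial endpoints. The AUC is the Mann–Whitney
concordance probability with ties counted one half, computed via midranks;
it equals the trapezoidal area under the polygon to machine precision. The
default AUC CI is Hanley–McNeil (closed form, desk-checkable); a DeLong
placement-based variance is available by flag and is the basis of the
paired two-marker comparison test, which additionally reports a
class-stratified bootstrap CI of the AUC difference (default B = 2000,
explicit seed).

Youden-optimal cutoffs maximise J = sens + spec − 1 over the midpoints
between consecutive distinct observed scores plus ±∞ sentinels. Midpoints
(rather than observed values) make the reported cutoff an interstitial
value such as 18.3 or 22.5, matching how such cutoffs are conventionally
reported. Ties in J are broken toward higher specificity, then toward the
lower cutoff, making the optimiser deterministic; for a degenerate stratum
where every score is tied, J = 0 at the +∞ sentinel (nobody called
positive). Cutoffs are optimised per stratum by default — pre- and
post-menopausal cutoffs genuinely differ — with fixed shared cutoffs
available through the pipeline config when cross-stratum count additivity
is wanted.

## Baseline comparisons

Continuous/ordinal variables use the Mann–Whitney U test: exact enumeration
when the pooled sample is tie-free and m·n ≤ 400, otherwise the
tie-corrected continuity-corrected normal approximation (delegated to
scipy.stats). Categorical 2×2 tables use Pearson chi-square *without* Yates
correction (df = 1) when all expected counts reach 5, otherwise Fisher's
exact test with the probability-mass two-sided rule (tables no more
probable than the observed are summed). The uncorrected chi-square and the
probability-mass Fisher rule are stated explicitly because the corrected /
doubling alternatives give visibly different third decimals on tables of
this size. Reported p-values display at 3 decimals, floored at "< 0.001".

## Synthetic cohorts

No patient-level data accompany the study design this package targets, so
the generator produces cohorts carrying the structure the analysis assumes,
calibrated to published group-level summaries:

- **Sizes and composition.** Defaults: 56 benign / 43 malignant; menopause
  Bernoulli(9/56) benign and Bernoulli(22/43) malignant; FIGO stage
  categorical (4, 8, 22, 9)/43 over stages 1–4 for malignant cases only.
- **Markers.** Per (marker, pathology) truncated log-normals:
  μ = ln(published median) — benign CA125 17, malignant 121, benign HE4
  47, malignant 114 — and σ = max(ln max − μ, μ − ln min)/3, so the
  published min–max range lies inside the central 99.7% band (μ ± 3σ),
  which is also the truncation band. Symmetric truncation preserves the
  median exactly. Medians are matched rather than means/SDs: a
  two-parameter family cannot match mean, SD and median simultaneously,
  and every downstream metric is rank-based, so the median (and the
  right-skew the log-normal provides, visible in the published
  mean ≫ median pattern) is what matters.
- **Correlation.** (ln CA125, ln HE4) are bivariate normal with one shared
  correlation ρ = 0.3 in both groups — a moderate positive dependence
  between two markers of the same disease process; no published joint
  information exists to calibrate it further, and it is configurable.
- **Age and symptoms.** Age is truncated normal (39 ± 14 benign,
  51 ± 16 malignant, range 17–79); symptom flags are independent Bernoullis
  at the published group rates. These exist to exercise the baseline module
  and are drawn independently of markers and of menopausal status.

What the generator does **not** emulate: any dependence of marker levels on
menopausal status or stage within pathology group, correlation between age
and menopause, or assay-specific measurement error. Consequently, passing
pipeline tests on synthetic data demonstrate the *machinery* (scoring,
optimisation, metric computation, stratification) under realistic marginal
distributions, not a patient-level reproduction of the original study: the
published AUCs (0.907 total ROMA), per-stratum cutoffs and the AUC-difference
p-value depend on the unpublished raw data and are covered only by a
property band — across 200 replicate cohorts at the study size the mean
ROMA AUC is expected (and tested) to lie in [0.80, 0.97].

Problem sizes used by the test and acceptance runs: calibration checks at
10⁴ per group, parameter recovery at 10⁵, discrimination bands over 200
replicates at 56/43. All draws come from `numpy.random.default_rng` with
explicit seeds; a (spec, seed) pair regenerates a byte-identical CSV.

## Numerical choices and edge cases

- ROMA(%) uses the two-branch logistic (100/(1+e^(−PI)) for PI ≥ 0, else
  100·e^PI/(1+e^PI)): no overflow, saturating to 0/100, never NaN. The
  logit round-trip is float64-exact to 1e−9 for |PI| ≲ 14; beyond that the
  percent representation itself limits recoverable precision (the
  complement symmetry ROMA(PI) + ROMA(−PI) = 100 holds throughout).
- Wilson bounds clamp the analytic 0/100 endpoints at x = 0 / x = n to kill
  float residue.
- Confusion-table metrics never round internally; one-decimal rounding is
  applied only in the presentation TSV layer. The report JSON carries full
  precision, and re-deriving the TSVs from it reproduces them byte for
  byte.
- The pipeline's canonical config (and hence the report digest) excludes
  the output directory, so the bundle content is independent of where it is
  written; rerunning with the same config and seed is byte-identical.

## Known limitations

- Single ROMA coefficient set (no assay-specific recalibrations); no
  borderline/multi-class outcome support; no prevalence-adjusted predictive
  values.
- Published LR and kappa CIs from studies of this kind do not always follow
  the Simel/asymptotic formulas implemented here (the procedures are often
  unnamed); point estimates are the comparable surface, and this package's
  CI methods are stated explicitly instead.
- Menopausal status is taken from the input column, never inferred from
  age; a QC helper flags pre-menopausal records above a configurable age
  for review only.
- The synthetic generator's independence assumptions (above) mean baseline
  tables from synthetic cohorts show the built-in marginal rates, not any
  realistic covariance between symptoms, age and markers.
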