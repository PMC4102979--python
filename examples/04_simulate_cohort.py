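"""Generate and summarise a calibrated synthetic adnexal-mass cohort.

The generator draws correlated log-normal CA125/HE4 values calibrated so
each group's median matches the published group medians (benign CA125 17,
malignant 121; benign HE4 47, malignant 114), with menopause, FIGO stage and
symptom flags at the published group rates.  Prints the group summary in
mean +/- SD, median (range) form.
"""

from romadx import default_spec, generate, summarize

cohort = generate(default_spec(), seed=1)
print(f"cohort: {cohort.n_benign} benign / {cohort.n_malignant} malignant, "
      f"{sum(r.is_postmenopausal for r in cohort)} post-menopausal\n")

table = summarize(cohort)
for _, row in table.iterrows():
    print(f"{row['marker']:>6} {row['group']:>9}: "
          f"{row['mean']:8.1f} +/- {row['sd']:7.1f}   "
          f"median {row['median']:7.1f}  ({row['min']:.1f} - {row['max']:.1f})")

print("\nAt n = 56/43 the sample medians scatter around the calibration")
print("targets; the malignant mean >> median pattern reflects the right-skew")
print("of both markers.")
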