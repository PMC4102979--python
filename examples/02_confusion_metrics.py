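"""Full diagnostic-metric suite from a confusion table.

Takes the ROMA total-cohort confusion table reported for a 99-patient
adnexal-mass case series (32 TP, 2 FP, 11 FN, 54 TN at the >= 18.3% cutoff)
and prints every metric the evaluation pipeline computes, with 95% CIs.
"""

from romadx import ConfusionTable, evaluate_table

ct = ConfusionTable(tp=32, fp=2, fn=11, tn=54)
ev = evaluate_table(ct, cutoff=18.3)

print(f"confusion table at ROMA >= 18.3%:  TP={ct.tp} FP={ct.fp} FN={ct.fn} TN={ct.tn}")
for name, m in ev.metrics.items():
    print(f"{name:>20}: {m.value:8.3f}  (95% CI {m.ci_low:.3f} - {m.ci_high:.3f})"
          f"  [{m.method}]")

print("\nProportions are percentages with Wilson score CIs; LR+/LR- and the")
print("diagnostic odds ratio use log-method CIs; kappa is chance-corrected")
print("agreement between the ROMA call and pathology.")
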