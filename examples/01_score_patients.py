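"""Score individual patients with the menopause-specific ROMA index.

Builds two patients with identical serum markers but different menopausal
status, and prints the predictive index (PI) and ROMA percentage for each:
ROMA uses different coefficient sets before and after menopause, so the same
CA125/HE4 pair maps to different risk levels.
"""

from romadx import roma_from_markers

for status in ("pre", "post"):
    res = roma_from_markers(he4=56.0, ca125=29.0, status=status)
    print(f"{status:>4}-menopausal: HE4=56 pmol/L, CA125=29 U/mL "
          f"-> PI = {res.pi:+.3f}, ROMA = {res.roma_percent:.2f}%")

print("\nROMA% is a probability-like malignancy score in (0, 100); the same")
print("markers score higher post-menopause because benign CA125/HE4 elevations")
print("are less common there.")
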