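"""ROMA (Risk of Ovarian Malignancy Algorithm) scoring.

ROMA combines serum HE4 (pmol/L) and CA125 (U/mL) into a menopause-specific
predictive index

    pre-menopause:  PI = -12.0 + 2.38*ln(HE4) + 0.0626*ln(CA125)
    post-menopause: PI = -8.09 + 1.04*ln(HE4) + 0.732*ln(CA125)

and expresses it as a probability-like percentage through the logistic
transform ROMA(%) = 100 * e^PI / (1 + e^PI).  Markers enter as raw assay
outputs, with no unit conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .cohort import Cohort, MenopausalStatus

__all__ = [
    "ROMA_COEFFICIENTS",
    "RomaResult",
    "predictive_index",
    "roma_percent",
    "roma_from_markers",
    "score_cohort",
]

#: (intercept, ln-HE4 coefficient, ln-CA125 coefficient) per menopausal status.
ROMA_COEFFICIENTS: dict[MenopausalStatus, tuple[float, float, float]] = {
    MenopausalStatus.PRE: (-12.0, 2.38, 0.0626),
    MenopausalStatus.POST: (-8.09, 1.04, 0.732),
}


@dataclass(frozen=True)
class RomaResult:
    """Predictive index and ROMA percentage for one patient."""

    pi: float
    roma_percent: float


def predictive_index(
    he4: float, ca125: float, status: MenopausalStatus | str
) -> float:
    """Menopause-specific linear predictor on the log-marker scale."""
    if isinstance(status, str):
        status = MenopausalStatus(status)
    if not he4 > 0:
        raise ValueError(f"he4 must be > 0, got {he4!r}")
    if not ca125 > 0:
        raise ValueError(f"ca125 must be > 0, got {ca125!r}")
    intercept, b_he4, b_ca125 = ROMA_COEFFICIENTS[status]
    return intercept + b_he4 * math.log(he4) + b_ca125 * math.log(ca125)


def roma_percent(pi: float) -> float:
    """Logistic transform of the predictive index, in percent.

    Saturates smoothly to 0 / 100 for extreme indices; never overflows.
    """
    if math.isnan(pi):
        raise ValueError("predictive index is NaN")
    # evaluate on the side that keeps exp() bounded
    if pi >= 0:
        return 100.0 / (1.0 + math.exp(-pi))
    e = math.exp(pi)
    return 100.0 * e / (1.0 + e)


def roma_from_markers(
    he4: float, ca125: float, status: MenopausalStatus | str
) -> RomaResult:
    pi = predictive_index(he4, ca125, status)
    return RomaResult(pi=pi, roma_percent=roma_percent(pi))


def score_cohort(cohort: Cohort) -> dict[str, RomaResult]:
    """ROMA result per patient id, dispatching on menopausal status."""
    out: dict[str, RomaResult] = {}
    for r in cohort:
        try:
            out[r.id] = roma_from_markers(r.he4, r.ca125, r.menopausal_status)
        except ValueError as exc:  # pragma: no cover - guarded by record invariants
            raise ValueError(f"patient {r.id}: {exc}") from exc
    return out


def marker_scores(cohort: Cohort, marker: str) -> dict[str, float]:
    """Per-patient score for ``marker`` in {'ca125', 'he4', 'roma'}.

    CA125 and HE4 are the raw serum values; 'roma' is the ROMA percentage.
    """
    marker = marker.lower()
    if marker == "ca125":
        return {r.id: r.ca125 for r in cohort}
    if marker == "he4":
        return {r.id: r.he4 for r in cohort}
    if marker == "roma":
        return {pid: res.roma_percent for pid, res in score_cohort(cohort).items()}
    raise ValueError(f"unknown marker {marker!r}; expected ca125, he4 or roma")


def truth_labels(cohort: Cohort) -> dict[str, bool]:
    """Per-patient malignancy indicator (True = epithelial ovarian cancer)."""
    return {r.id: r.is_malignant for r in cohort}
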