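"""Synthetic adnexal-mass cohorts calibrated to published group summaries.

No patient-level data accompany the study this pipeline reimplements, so
this module generates cohorts carrying the statistical structure the
analysis assumes: a benign and a malignant (epithelial ovarian cancer)
group of configurable size, menopausal status by group-specific Bernoulli
draws, FIGO stage for the malignant group, and correlated right-skewed
CA125/HE4 marker values.

Markers are truncated log-normals.  For each (marker, pathology) pair the
log-mean equals the log of the published group median, and the log-SD is
set so the published min-max range sits inside the central 99.7% band
(mu +/- 3 sigma), which is also the truncation band; symmetric truncation
preserves the median.  Medians are matched rather than means/SDs because a
two-parameter family cannot match all three and every downstream metric is
rank-based.  Joint (ln CA125, ln HE4) draws are bivariate normal with one
shared correlation ``rho`` in both groups.

Ages, menopause rates, stage distribution and symptom prevalences default to
the published cohort composition (56 benign / 43 malignant, 9 vs 22
post-menopausal, stages 4:8:22:9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import Cohort, MenopausalStatus, PatientRecord, Pathology, SYMPTOM_FLAGS
from .score import score_cohort

__all__ = [
    "LogNormalParams",
    "SyntheticSpec",
    "default_spec",
    "generate",
    "summarize",
]


@dataclass(frozen=True)
class LogNormalParams:
    """Truncated log-normal marginal for one marker in one pathology group.

    ``mu``/``sigma`` are on the natural-log scale; draws are rejected
    outside ``(ln_low, ln_high)``.
    """

    mu: float
    sigma: float
    ln_low: float
    ln_high: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not self.ln_low < self.ln_high:
            raise ValueError("truncation range must be non-empty")

    @property
    def median(self) -> float:
        return math.exp(self.mu)


def _params_from_summary(median: float, low: float, high: float) -> LogNormalParams:
    """Solve (mu, sigma) from a printed median and range.

    mu = ln(median); sigma = max(ln high - mu, mu - ln low) / 3, so the
    printed range lies inside the central 99.7% band, which doubles as the
    truncation band.
    """
    if not 0 < low <= median <= high:
        raise ValueError("need 0 < low <= median <= high")
    mu = math.log(median)
    sigma = max(math.log(high) - mu, mu - math.log(low)) / 3.0
    return LogNormalParams(mu=mu, sigma=sigma, ln_low=mu - 3 * sigma, ln_high=mu + 3 * sigma)


#: Published per-group marker medians and ranges used for calibration.
_MARKER_SUMMARIES = {
    ("ca125", "benign"): (17.0, 2.0, 140.0),
    ("ca125", "malignant"): (121.0, 3.0, 7169.0),
    ("he4", "benign"): (47.0, 5.0, 97.0),
    ("he4", "malignant"): (114.0, 26.0, 1500.0),
}

_AGE_PARAMS = {  # (mean, sd), truncated to (17, 79)
    "benign": (39.0, 14.0),
    "malignant": (51.0, 16.0),
}
_AGE_RANGE = (17.0, 79.0)

_SYMPTOM_RATES = {  # published group prevalences
    "vaginal_bleeding": {"benign": 13 / 56, "malignant": 10 / 43},
    "pain": {"benign": 32 / 56, "malignant": 21 / 43},
    "distension": {"benign": 7 / 56, "malignant": 18 / 43},
    "weight_loss": {"benign": 0 / 56, "malignant": 3 / 43},
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic cohort."""

    n_benign: int = 56
    n_malignant: int = 43
    menopause_prob: dict = field(
        default_factory=lambda: {"benign": 9 / 56, "malignant": 22 / 43}
    )
    marker_params: dict = field(
        default_factory=lambda: {
            key: _params_from_summary(*summ) for key, summ in _MARKER_SUMMARIES.items()
        }
    )
    rho: float = 0.3
    stage_probs: tuple[float, float, float, float] = (4 / 43, 8 / 43, 22 / 43, 9 / 43)
    symptom_rates: dict = field(default_factory=lambda: dict(_SYMPTOM_RATES))

    def __post_init__(self) -> None:
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ValueError("group sizes must be non-negative")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        for g, p in self.menopause_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"menopause_prob[{g!r}] outside [0, 1]")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9 or min(self.stage_probs) < 0:
            raise ValueError("stage_probs must be a probability vector over stages 1-4")


def default_spec(**overrides) -> SyntheticSpec:
    """Spec calibrated to the published cohort; keyword overrides allowed."""
    return replace(SyntheticSpec(), **overrides) if overrides else SyntheticSpec()


def _draw_markers(
    rng: np.random.Generator, spec: SyntheticSpec, group: str, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Truncated correlated (CA125, HE4) draws for one group, by rejection."""
    p_ca = spec.marker_params[("ca125", group)]
    p_he = spec.marker_params[("he4", group)]
    cov = np.array([[1.0, spec.rho], [spec.rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    ca = np.empty(n)
    he = np.empty(n)
    filled = 0
    while filled < n:
        batch = max(2 * (n - filled), 16)
        z = chol @ rng.standard_normal((2, batch))
        ln_ca = p_ca.mu + p_ca.sigma * z[0]
        ln_he = p_he.mu + p_he.sigma * z[1]
        ok = (
            (ln_ca >= p_ca.ln_low)
            & (ln_ca <= p_ca.ln_high)
            & (ln_he >= p_he.ln_low)
            & (ln_he <= p_he.ln_high)
        )
        take = min(int(ok.sum()), n - filled)
        ca[filled : filled + take] = np.exp(ln_ca[ok][:take])
        he[filled : filled + take] = np.exp(ln_he[ok][:take])
        filled += take
    return ca, he


def _draw_age(rng: np.random.Generator, group: str, n: int) -> np.ndarray:
    mean, sd = _AGE_PARAMS[group]
    lo, hi = _AGE_RANGE
    out = np.empty(n)
    filled = 0
    while filled < n:
        x = rng.normal(mean, sd, size=max(2 * (n - filled), 16))
        x = x[(x >= lo) & (x <= hi)]
        take = min(len(x), n - filled)
        out[filled : filled + take] = x[:take]
        filled += take
    return out


def generate(spec: SyntheticSpec, seed: int | None = None) -> Cohort:
    """Generate one cohort; deterministic for a given (spec, seed)."""
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    counter = 0
    for group, n, pathology in (
        ("benign", spec.n_benign, Pathology.BENIGN),
        ("malignant", spec.n_malignant, Pathology.MALIGNANT),
    ):
        ca, he = _draw_markers(rng, spec, group, n)
        age = _draw_age(rng, group, n)
        post = rng.random(n) < spec.menopause_prob[group]
        if pathology is Pathology.MALIGNANT:
            stages = rng.choice([1, 2, 3, 4], size=n, p=spec.stage_probs)
        symptom_draws = {
            flag: rng.random(n) < spec.symptom_rates[flag][group]
            for flag in SYMPTOM_FLAGS
        }
        for i in range(n):
            counter += 1
            records.append(
                PatientRecord(
                    id=f"S{counter:04d}",
                    age=round(float(age[i]), 1),
                    menopausal_status=(
                        MenopausalStatus.POST if post[i] else MenopausalStatus.PRE
                    ),
                    ca125=round(float(ca[i]), 2),
                    he4=round(float(he[i]), 2),
                    pathology=pathology,
                    stage=int(stages[i]) if pathology is Pathology.MALIGNANT else None,
                    symptoms=frozenset(
                        flag for flag in SYMPTOM_FLAGS if symptom_draws[flag][i]
                    ),
                )
            )
    return Cohort(records, provenance=f"synthetic(seed={seed})")


def summarize(cohort: Cohort, include_roma: bool = True) -> pd.DataFrame:
    """Per-marker, per-group summary: mean, SD, median, min, max, n.

    Mirrors the mean +/- SD, median (range) presentation of published
    biomarker tables.  A single-record group reports SD as NaN (undefined);
    an empty group is omitted with an ``n = 0`` row.
    """
    roma = score_cohort(cohort) if include_roma else {}
    rows = []
    markers = ["ca125", "he4"] + (["roma"] if include_roma else [])
    for group in ("benign", "malignant"):
        members = [r for r in cohort if r.pathology.value == group]
        for marker in markers:
            if marker == "roma":
                vals = np.array([roma[r.id].roma_percent for r in members])
            else:
                vals = np.array([getattr(r, marker) for r in members])
            if len(vals) == 0:
                rows.append(
                    {"marker": marker, "group": group, "n": 0, "mean": math.nan,
                     "sd": math.nan, "median": math.nan, "min": math.nan,
                     "max": math.nan}
                )
                continue
            rows.append(
                {
                    "marker": marker,
                    "group": group,
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else math.nan,
                    "median": float(np.median(vals)),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }
            )
    return pd.DataFrame(rows)
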