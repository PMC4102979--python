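"""Confusion tables and the full diagnostic-metric suite with 95% CIs.

Given per-patient scores, pathology truth and a cutoff, this module builds a
2x2 confusion table (positive call at score >= cutoff) and computes
sensitivity, specificity, predictive values, diagnostic accuracy (all as
percentages with Wilson score intervals), positive/negative likelihood
ratios (log-method CIs), the diagnostic odds ratio, and unweighted Cohen's
kappa against pathology.

Zero denominators never raise: the affected metric comes back tagged
``undefined`` (value NaN, or +inf for ratio metrics with an empty
denominator cell) so stratified batch runs always complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ConfusionTable",
    "MetricEstimate",
    "MarkerEvaluation",
    "wilson_interval",
    "make_confusion",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "diagnostic_accuracy",
    "likelihood_ratios",
    "diagnostic_odds",
    "cohens_kappa",
    "evaluate_marker",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FP/FN/TN counts for one marker at one cutoff within one stratum."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("confusion table is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


@dataclass(frozen=True)
class MetricEstimate:
    """Point estimate with a 95% CI and a tag naming the CI procedure.

    ``value`` is in percent for proportion metrics, on the ratio scale for
    LR/DOR, and in [-1, 1] for kappa.  An undefined metric carries
    ``method`` starting with ``"undefined"`` and NaN/inf placeholders.
    """

    value: float
    ci_low: float
    ci_high: float
    method: str
    n_effective: int

    @property
    def defined(self) -> bool:
        return not self.method.startswith("undefined")

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        return tuple(round(v, ndigits) for v in (self.value, self.ci_low, self.ci_high))

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
            "n_effective": self.n_effective,
        }


def wilson_interval(x: int, n: int, z: float = Z95) -> tuple[float, float]:
    """Wilson score 95% CI for the proportion x/n, as fractions in [0, 1].

    Obtained by inverting the normal score test; the lower bound is exactly 0
    when x = 0 and the upper exactly 1 when x = n.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    p = x / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    # centre - half is exactly 0 for x = 0 (and centre + half exactly 1 for
    # x = n) analytically; clamp the float residue
    lo = 0.0 if x == 0 else max(0.0, centre - half)
    hi = 1.0 if x == n else min(1.0, centre + half)
    return lo, hi


def make_confusion(
    scores: Mapping[str, float],
    truth: Mapping[str, bool],
    cutoff: float,
) -> ConfusionTable:
    """Threshold scores at ``cutoff`` (>= is positive) against pathology."""
    if set(scores) != set(truth):
        only_s = sorted(set(scores) - set(truth))[:3]
        only_t = sorted(set(truth) - set(scores))[:3]
        raise ValueError(
            f"score/truth id mismatch (e.g. scores-only {only_s}, truth-only {only_t})"
        )
    if not math.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff!r}")
    tp = fp = fn = tn = 0
    for pid, s in scores.items():
        positive = s >= cutoff
        if truth[pid]:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def _proportion_metric(x: int, n: int, name: str) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(
            value=math.nan,
            ci_low=math.nan,
            ci_high=math.nan,
            method=f"undefined:{name}-zero-denominator",
            n_effective=0,
        )
    lo, hi = wilson_interval(x, n)
    return MetricEstimate(
        value=100.0 * x / n,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
        method="wilson",
        n_effective=n,
    )


def sensitivity(ct: ConfusionTable) -> MetricEstimate:
    """True-positive rate among the diseased, percent with Wilson CI."""
    return _proportion_metric(ct.tp, ct.n_diseased, "sensitivity")


def specificity(ct: ConfusionTable) -> MetricEstimate:
    """True-negative rate among the non-diseased, percent with Wilson CI."""
    return _proportion_metric(ct.tn, ct.n_healthy, "specificity")


def ppv(ct: ConfusionTable) -> MetricEstimate:
    """Positive predictive value at the study prevalence."""
    return _proportion_metric(ct.tp, ct.tp + ct.fp, "ppv")


def npv(ct: ConfusionTable) -> MetricEstimate:
    """Negative predictive value at the study prevalence."""
    return _proportion_metric(ct.tn, ct.tn + ct.fn, "npv")


def diagnostic_accuracy(ct: ConfusionTable) -> MetricEstimate:
    """Proportion of all subjects classified correctly."""
    return _proportion_metric(ct.tp + ct.tn, ct.n, "diagnostic_accuracy")


def likelihood_ratios(ct: ConfusionTable) -> tuple[MetricEstimate, MetricEstimate]:
    """(LR+, LR-) on unrounded proportions, CIs by the log-transform method.

    SE(ln LR+) = sqrt((1-sens)/tp + spec/fp); analogously for LR-.  With no
    false positives LR+ is +inf (one-sided lower bound only); with no false
    negatives LR- is exactly 0.
    """
    sens = ct.tp / ct.n_diseased if ct.n_diseased else math.nan
    spec = ct.tn / ct.n_healthy if ct.n_healthy else math.nan
    if not (math.isfinite(sens) and math.isfinite(spec)):
        und = MetricEstimate(math.nan, math.nan, math.nan, "undefined:lr-empty-class", 0)
        return und, und

    if ct.fp == 0:
        if ct.tp == 0:
            lr_pos = MetricEstimate(
                math.nan, math.nan, math.nan, "undefined:lr+-no-positives", ct.n
            )
        else:
            lr_pos = MetricEstimate(
                math.inf, math.nan, math.inf, "log-method:one-sided-infinite", ct.n
            )
    else:
        value = sens / (1.0 - spec)
        if ct.tp == 0:
            lr_pos = MetricEstimate(0.0, 0.0, math.nan, "log-method:one-sided-zero", ct.n)
        else:
            se = math.sqrt((1.0 - sens) / ct.tp + spec / ct.fp)
            lr_pos = MetricEstimate(
                value,
                value * math.exp(-Z95 * se),
                value * math.exp(Z95 * se),
                "log-method",
                ct.n,
            )

    if ct.fn == 0:
        lr_neg = MetricEstimate(0.0, 0.0, math.nan, "log-method:one-sided-zero", ct.n)
    elif ct.tn == 0:
        lr_neg = MetricEstimate(
            math.inf, math.nan, math.inf, "log-method:one-sided-infinite", ct.n
        )
    else:
        value = (1.0 - sens) / spec
        se = math.sqrt(sens / ct.fn + (1.0 - spec) / ct.tn)
        lr_neg = MetricEstimate(
            value,
            value * math.exp(-Z95 * se),
            value * math.exp(Z95 * se),
            "log-method",
            ct.n,
        )
    return lr_pos, lr_neg


def diagnostic_odds(
    ct: ConfusionTable, continuity_correction: bool = False
) -> MetricEstimate:
    """Diagnostic odds ratio (TP*TN)/(FP*FN), CI on the log scale.

    With an empty FP or FN cell the DOR is +inf (tagged) unless a Haldane
    0.5 continuity correction is explicitly requested.
    """
    tp, fp, fn, tn = ct.as_tuple()
    if continuity_correction and (fp == 0 or fn == 0 or tp == 0 or tn == 0):
        tp, fp, fn, tn = (c + 0.5 for c in (tp, fp, fn, tn))
        method = "log-method:haldane-corrected"
    elif fp == 0 or fn == 0:
        return MetricEstimate(
            math.inf, math.nan, math.inf, "undefined:dor-empty-error-cell", ct.n
        )
    elif tp == 0 or tn == 0:
        return MetricEstimate(0.0, 0.0, math.nan, "undefined:dor-empty-hit-cell", ct.n)
    else:
        method = "log-method"
    dor = (tp * tn) / (fp * fn)
    se = math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
    return MetricEstimate(
        dor, dor * math.exp(-Z95 * se), dor * math.exp(Z95 * se), method, ct.n
    )


def cohens_kappa(ct: ConfusionTable) -> MetricEstimate:
    """Unweighted Cohen's kappa between the test call and pathology.

    kappa = (po - pe) / (1 - pe) with the marginal-product expected
    agreement; CI is the asymptotic normal interval
    kappa +/- 1.96 * sqrt(po(1-po) / (n (1-pe)^2)).
    """
    tp, fp, fn, tn = ct.as_tuple()
    n = ct.n
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    if pe == 1.0:
        return MetricEstimate(
            math.nan, math.nan, math.nan, "undefined:kappa-degenerate-margins", n
        )
    kappa = (po - pe) / (1.0 - pe)
    se = math.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    return MetricEstimate(
        kappa, kappa - Z95 * se, kappa + Z95 * se, "asymptotic-normal", n
    )


#: Metric rows in report order (the layout of the published summary tables).
METRIC_ORDER = (
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "diagnostic_accuracy",
    "lr_positive",
    "lr_negative",
    "diagnostic_odds",
    "cohens_kappa",
)


@dataclass(frozen=True)
class MarkerEvaluation:
    """Full metric table for one marker at one cutoff."""

    cutoff: float
    table: ConfusionTable
    metrics: Mapping[str, MetricEstimate] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "confusion": {
                "tp": self.table.tp,
                "fp": self.table.fp,
                "fn": self.table.fn,
                "tn": self.table.tn,
            },
            "metrics": {k: self.metrics[k].to_dict() for k in METRIC_ORDER},
        }


def evaluate_marker(
    scores: Mapping[str, float],
    truth: Mapping[str, bool],
    cutoff: float,
) -> MarkerEvaluation:
    """Confusion table plus the complete metric suite at one cutoff."""
    ct = make_confusion(scores, truth, cutoff)
    return evaluate_table(ct, cutoff=cutoff)


def evaluate_table(ct: ConfusionTable, cutoff: float = math.nan) -> MarkerEvaluation:
    """Metric suite for an already-built confusion table."""
    lr_pos, lr_neg = likelihood_ratios(ct)
    metrics = {
        "sensitivity": sensitivity(ct),
        "specificity": specificity(ct),
        "ppv": ppv(ct),
        "npv": npv(ct),
        "diagnostic_accuracy": diagnostic_accuracy(ct),
        "lr_positive": lr_pos,
        "lr_negative": lr_neg,
        "diagnostic_odds": diagnostic_odds(ct),
        "cohens_kappa": cohens_kappa(ct),
    }
    return MarkerEvaluation(cutoff=cutoff, table=ct, metrics=metrics)
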