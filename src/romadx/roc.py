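"""Empirical ROC curves, AUC, Youden-optimal cutoffs and paired AUC tests.

All operations take per-patient scores and boolean truth labels (True =
diseased) keyed by patient id, matching the scoring module.  The positive
call is score >= cutoff throughout, consistent with the diagnostics module.

The AUC is the empirical Mann-Whitney probability that a random diseased
subject outscores a random healthy one, with ties counted one half.  Its
default CI is Hanley-McNeil (closed form, exponential approximation); a
DeLong structural-component variance is available by flag and drives the
paired two-marker comparison test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .diagnostics import MetricEstimate, Z95

__all__ = [
    "RocCurve",
    "CutoffResult",
    "DeLongComparison",
    "roc_curve",
    "auc",
    "youden_cutoff",
    "compare_auc",
]


def _split(scores: Mapping[str, float], truth: Mapping[str, bool]):
    if set(scores) != set(truth):
        raise ValueError("score/truth id mismatch")
    pos = np.array([s for pid, s in scores.items() if truth[pid]], dtype=float)
    neg = np.array([s for pid, s in scores.items() if not truth[pid]], dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(
            f"both classes must be non-empty (diseased={len(pos)}, healthy={len(neg)})"
        )
    return pos, neg


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC polygon: one vertex per distinct observed score.

    ``cutoffs`` descend from +inf (nobody positive) to the minimum observed
    score (everybody positive), so (sensitivity, 1-specificity) runs
    monotonically from (0, 0) to (1, 1).
    """

    cutoffs: tuple[float, ...]
    sensitivity: tuple[float, ...]
    one_minus_specificity: tuple[float, ...]
    n_diseased: int
    n_healthy: int

    def trapezoidal_area(self) -> float:
        return float(np.trapezoid(self.sensitivity, self.one_minus_specificity))


@dataclass(frozen=True)
class CutoffResult:
    """Youden-optimal operating point of an empirical ROC curve."""

    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float


def roc_curve(scores: Mapping[str, float], truth: Mapping[str, bool]) -> RocCurve:
    """Empirical ROC curve with a vertex at every distinct observed score."""
    pos, neg = _split(scores, truth)
    n1, n0 = len(pos), len(neg)
    thresholds = np.concatenate(([np.inf], np.unique(np.concatenate([pos, neg]))[::-1]))
    sens = [(pos >= t).mean() for t in thresholds]
    fpr = [(neg >= t).mean() for t in thresholds]
    return RocCurve(
        cutoffs=tuple(float(t) for t in thresholds),
        sensitivity=tuple(float(s) for s in sens),
        one_minus_specificity=tuple(float(f) for f in fpr),
        n_diseased=n1,
        n_healthy=n0,
    )


def _auc_value(pos: np.ndarray, neg: np.ndarray) -> float:
    # Mann-Whitney via midranks: ties contribute 1/2 per pair
    n1, n0 = len(pos), len(neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """Placement values: V10 (per diseased) and V01 (per healthy)."""
    # midrank trick: placement of each diseased score among healthy scores
    order = np.concatenate([pos, neg])
    n1, n0 = len(pos), len(neg)
    all_r = stats.rankdata(order)
    pos_r = stats.rankdata(pos)
    neg_r = stats.rankdata(neg)
    v10 = (all_r[:n1] - pos_r) / n0
    v01 = 1.0 - (all_r[n1:] - neg_r) / n1
    return v10, v01


def auc(
    scores: Mapping[str, float],
    truth: Mapping[str, bool],
    ci_method: str = "hanley-mcneil",
) -> MetricEstimate:
    """Empirical AUC with a 95% CI, clipped to [0, 1].

    ``ci_method`` is ``"hanley-mcneil"`` (default) or ``"delong"``.
    """
    pos, neg = _split(scores, truth)
    n1, n0 = len(pos), len(neg)
    a = _auc_value(pos, neg)
    if ci_method == "hanley-mcneil":
        q1 = a / (2.0 - a)
        q2 = 2.0 * a * a / (1.0 + a)
        var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (
            n1 * n0
        )
    elif ci_method == "delong":
        v10, v01 = _delong_components(pos, neg)
        var = np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n0
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    se = math.sqrt(max(var, 0.0))
    return MetricEstimate(
        value=a,
        ci_low=max(0.0, a - Z95 * se),
        ci_high=min(1.0, a + Z95 * se),
        method=ci_method,
        n_effective=n1 + n0,
    )


def youden_cutoff(
    scores: Mapping[str, float], truth: Mapping[str, bool]
) -> CutoffResult:
    """Cutoff maximising Youden's J = sensitivity + specificity - 1.

    Candidates are the midpoints between consecutive distinct observed
    scores plus the +/-inf sentinels (nobody / everybody positive).  Ties in
    J are broken toward higher specificity, then toward the lower cutoff, so
    the result is deterministic.
    """
    pos, neg = _split(scores, truth)
    uniq = np.unique(np.concatenate([pos, neg]))
    candidates = [math.inf, -math.inf]
    candidates.extend((uniq[:-1] + uniq[1:]) / 2.0)

    best: tuple[float, float, float] | None = None  # (J, spec, -cutoff) maximised
    best_result: CutoffResult | None = None
    for c in candidates:
        sens = float((pos >= c).mean())
        spec = float((neg < c).mean())
        j = sens + spec - 1.0
        key = (j, spec, -c)
        if best is None or key > best:
            best = key
            best_result = CutoffResult(
                cutoff=float(c), youden_j=j, sensitivity=sens, specificity=spec
            )
    assert best_result is not None
    return best_result


@dataclass(frozen=True)
class DeLongComparison:
    """Paired comparison of two markers' AUCs on the same subjects."""

    auc_a: float
    auc_b: float
    difference: float
    z: float
    p_value: float
    bootstrap_ci: tuple[float, float] | None = None


def compare_auc(
    scores_a: Mapping[str, float],
    scores_b: Mapping[str, float],
    truth: Mapping[str, bool],
    n_bootstrap: int = 2000,
    seed: int | None = None,
) -> DeLongComparison:
    """DeLong paired test for the difference of two correlated AUCs.

    Both score maps must cover exactly the subjects in ``truth``.  When
    ``n_bootstrap`` > 0 a stratified bootstrap CI for the AUC difference is
    also reported (resampling patients within class, ``seed`` required for
    reproducibility).
    """
    if set(scores_a) != set(truth) or set(scores_b) != set(truth):
        raise ValueError("paired comparison requires identical subject ids")
    ids_pos = [pid for pid in truth if truth[pid]]
    ids_neg = [pid for pid in truth if not truth[pid]]
    if not ids_pos or not ids_neg:
        raise ValueError("both classes must be non-empty")

    pa = np.array([scores_a[i] for i in ids_pos])
    na = np.array([scores_a[i] for i in ids_neg])
    pb = np.array([scores_b[i] for i in ids_pos])
    nb = np.array([scores_b[i] for i in ids_neg])
    n1, n0 = len(pa), len(na)

    auc_a = _auc_value(pa, na)
    auc_b = _auc_value(pb, nb)
    v10a, v01a = _delong_components(pa, na)
    v10b, v01b = _delong_components(pb, nb)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    )
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        z = diff / math.sqrt(var)
    p = 1.0 if diff == 0 else 2.0 * stats.norm.sf(abs(z))

    boot_ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        diffs = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            ip = rng.integers(0, n1, n1)
            ineg = rng.integers(0, n0, n0)
            diffs[b] = _auc_value(pa[ip], na[ineg]) - _auc_value(pb[ip], nb[ineg])
        lo, hi = np.percentile(diffs, [2.5, 97.5])
        boot_ci = (float(lo), float(hi))

    return DeLongComparison(
        auc_a=auc_a,
        auc_b=auc_b,
        difference=diff,
        z=float(z),
        p_value=float(min(p, 1.0)),
        bootstrap_ci=boot_ci,
    )
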