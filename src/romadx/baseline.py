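"""Baseline group comparisons: Mann-Whitney U, chi-square and Fisher exact.

These reproduce the benign-vs-malignant comparisons of demographic and
symptom variables: Mann-Whitney for continuous/ordinal measures, Pearson
chi-square (uncorrected by default) for categorical 2x2 tables with adequate
expected counts, and the Fisher exact test otherwise.  The heavy lifting is
delegated to scipy.stats; this module fixes the conventions (two-sided
everywhere, no Yates correction unless asked, exact Mann-Whitney enumeration
for small tie-free samples) and the tabular report shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, SYMPTOM_FLAGS

__all__ = [
    "TwoByTwo",
    "mann_whitney",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "expected_counts",
    "baseline_table",
    "format_p",
]

#: Largest m*n for which the exact Mann-Whitney null is enumerated (tie-free).
EXACT_MW_LIMIT = 400


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 count table; rows = group (benign, malignant), cols = (absent, present)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (of the first sample) and a two-sided p-value.

    Exact enumeration when the samples are tie-free and m*n <= 400;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    small = len(x) * len(y) <= EXACT_MW_LIMIT
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def expected_counts(t: TwoByTwo) -> np.ndarray:
    """Expected cell counts under independence."""
    arr = t.as_array().astype(float)
    rows = arr.sum(axis=1, keepdims=True)
    cols = arr.sum(axis=0, keepdims=True)
    return rows @ cols / t.total


def chi_square_2x2(t: TwoByTwo, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square (df = 1), uncorrected by default.

    A zero row or column margin leaves the statistic undefined (NaN, p NaN).
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return math.nan, math.nan
    stat, p, _, _ = stats.chi2_contingency(arr, correction=yates)
    return float(stat), float(p)


def fisher_exact_2x2(t: TwoByTwo) -> float:
    """Fisher exact two-sided p by the probability-mass rule.

    Sums hypergeometric tables no more probable than the observed one; with
    a zero margin every table is the observed one and p = 1.
    """
    _, p = stats.fisher_exact(t.as_array(), alternative="two-sided")
    return float(min(p, 1.0))


def format_p(p: float, floor: float = 0.001) -> str:
    """Report-style p-value: 3 decimals, floored display below ``floor``."""
    if math.isnan(p):
        return "NA"
    if p < floor:
        return f"< {floor:g}"
    return f"{p:.3f}"


def _mw_row(name: str, benign: np.ndarray, malignant: np.ndarray) -> dict:
    u, p = mann_whitney(benign, malignant)
    def summ(v: np.ndarray) -> str:
        return (
            f"{v.mean():.1f} +/- {v.std(ddof=1):.1f}; "
            f"{np.median(v):.1f} ({v.min():g} - {v.max():g})"
        )
    return {
        "variable": name,
        "benign": summ(benign),
        "malignant": summ(malignant),
        "test": "mann-whitney",
        "statistic": u,
        "p_value": p,
        "p_display": format_p(p),
    }


def _categorical_row(
    name: str, t: TwoByTwo, min_expected: float = 5.0
) -> dict:
    """Chi-square when all expected counts reach ``min_expected``, else Fisher."""
    if (expected_counts(t) >= min_expected).all():
        stat, p = chi_square_2x2(t)
        test = "chi-square"
    else:
        stat, p = math.nan, fisher_exact_2x2(t)
        test = "fisher-exact"
    n_b = t.a + t.b
    n_m = t.c + t.d
    return {
        "variable": name,
        "benign": f"{t.b} ({100 * t.b / n_b:.1f}%)" if n_b else "NA",
        "malignant": f"{t.d} ({100 * t.d / n_m:.1f}%)" if n_m else "NA",
        "test": test,
        "statistic": stat,
        "p_value": p,
        "p_display": format_p(p),
    }


def baseline_table(cohort: Cohort) -> pd.DataFrame:
    """Benign-vs-malignant comparison table for age, menopause and symptoms.

    Continuous variables use Mann-Whitney; binary ones use chi-square when
    expected counts allow, Fisher exact otherwise.  Missing symptom columns
    are simply skipped.
    """
    benign = [r for r in cohort if not r.is_malignant]
    malignant = [r for r in cohort if r.is_malignant]
    if not benign or not malignant:
        raise ValueError("baseline comparison needs both pathology groups")
    rows = [
        _mw_row(
            "age",
            np.array([r.age for r in benign]),
            np.array([r.age for r in malignant]),
        )
    ]
    post_b = sum(r.is_postmenopausal for r in benign)
    post_m = sum(r.is_postmenopausal for r in malignant)
    rows.append(
        _categorical_row(
            "menopause",
            TwoByTwo(len(benign) - post_b, post_b, len(malignant) - post_m, post_m),
        )
    )
    for flag in SYMPTOM_FLAGS:
        f_b = sum(flag in r.symptoms for r in benign)
        f_m = sum(flag in r.symptoms for r in malignant)
        if f_b == 0 and f_m == 0:
            continue
        rows.append(
            _categorical_row(
                flag,
                TwoByTwo(len(benign) - f_b, f_b, len(malignant) - f_m, f_m),
            )
        )
    return pd.DataFrame(rows)
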