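"""ROC curve, AUC, Youden cutoff and paired AUC comparison."""

from __future__ import annotations

import math

import numpy as np
import pytest

from romadx import auc, compare_auc, roc_curve, youden_cutoff


def _maps(pos, neg):
    scores = {}
    truth = {}
    for i, s in enumerate(pos):
        scores[f"d{i}"] = float(s)
        truth[f"d{i}"] = True
    for i, s in enumerate(neg):
        scores[f"h{i}"] = float(s)
        truth[f"h{i}"] = False
    return scores, truth


def brute_force_auc(pos, neg):
    """All-pairs concordance with ties counted one half."""
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation_passes_through_top_left(self):
        scores, truth = _maps([1, 2], [0])
        c = roc_curve(scores, truth)
        idx = c.cutoffs.index(1.0)
        assert c.sensitivity[idx] == 1.0
        assert c.one_minus_specificity[idx] == 0.0

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        scores, truth = _maps(rng.integers(0, 10, 20), rng.integers(0, 10, 15))
        c = roc_curve(scores, truth)
        assert (c.sensitivity[0], c.one_minus_specificity[0]) == (0.0, 0.0)
        assert (c.sensitivity[-1], c.one_minus_specificity[-1]) == (1.0, 1.0)
        assert all(a <= b for a, b in zip(c.sensitivity, c.sensitivity[1:]))
        assert all(
            a <= b
            for a, b in zip(c.one_minus_specificity, c.one_minus_specificity[1:])
        )

    def test_tied_score_moves_both_axes(self):
        scores, truth = _maps([5], [5])
        c = roc_curve(scores, truth)
        idx = c.cutoffs.index(5.0)
        assert c.sensitivity[idx] == 1.0 and c.one_minus_specificity[idx] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            roc_curve({"a": 1.0}, {"a": True})


class TestAuc:
    def test_textbook_values(self):
        assert auc(*_maps([2, 3], [0, 1])).value == 1.0
        assert auc(*_maps([1, 1], [1, 1, 1])).value == 0.5
        assert auc(*_maps([3, 5], [4])).value == 0.5  # one concordant, one discordant

    def test_equals_trapezoidal_area_under_curve(self):
        rng = np.random.default_rng(42)
        scores, truth = _maps(rng.normal(1, 1, 30), rng.normal(0, 1, 25))
        c = roc_curve(scores, truth)
        assert auc(scores, truth).value == pytest.approx(
            c.trapezoidal_area(), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        pos = rng.integers(0, 20, 15)
        neg = rng.integers(0, 20, 12)
        a = auc(*_maps(pos, neg)).value
        b = auc(*_maps(np.exp(pos / 5.0), np.exp(neg / 5.0))).value
        assert a == pytest.approx(b, abs=1e-12)

    def test_delong_ci_variant(self):
        scores, truth = _maps([2, 3, 5, 8], [1, 2, 4])
        hm = auc(scores, truth, ci_method="hanley-mcneil")
        dl = auc(scores, truth, ci_method="delong")
        assert hm.value == dl.value
        assert 0.0 <= dl.ci_low <= dl.value <= dl.ci_high <= 1.0
        with pytest.raises(ValueError, match="ci_method"):
            auc(scores, truth, ci_method="bootstrap")


class TestYoudenCutoff:
    def test_separated_classes_split_at_midpoint(self):
        res = youden_cutoff(*_maps([30, 40], [10, 20]))
        assert res.cutoff == 25.0 and res.youden_j == 1.0

    def test_all_tied_scores_give_zero_j_at_sentinel(self):
        res = youden_cutoff(*_maps([7, 7], [7, 7, 7]))
        assert res.youden_j == 0.0
        assert math.isinf(res.cutoff)

    def test_hand_enumerated_example(self):
        # candidates around {10, 20, 21, 24, 26, 30}: J peaks at 25
        res = youden_cutoff(*_maps([20, 26, 30], [10, 21, 24]))
        assert res.cutoff == 25.0
        assert res.sensitivity == pytest.approx(2 / 3)
        assert res.specificity == 1.0

    def test_j_matches_curve_vertical_distance(self):
        rng = np.random.default_rng(5)
        scores, truth = _maps(rng.normal(1, 1, 25), rng.normal(0, 1, 30))
        res = youden_cutoff(scores, truth)
        c = roc_curve(scores, truth)
        max_gap = max(
            s - f for s, f in zip(c.sensitivity, c.one_minus_specificity)
        )
        assert res.youden_j == pytest.approx(max_gap, abs=1e-12)

    def test_monotone_transform_moves_cutoff_not_j(self):
        rng = np.random.default_rng(9)
        pos = rng.integers(0, 15, 12)
        neg = rng.integers(0, 15, 10)
        r1 = youden_cutoff(*_maps(pos, neg))
        r2 = youden_cutoff(*_maps(pos * 3 + 2, neg * 3 + 2))
        assert r1.youden_j == pytest.approx(r2.youden_j, abs=1e-12)


class TestCompareAuc:
    def test_identical_scores_give_p_one(self):
        scores, truth = _maps([2, 3, 9], [1, 4])
        res = compare_auc(scores, scores, truth, n_bootstrap=0)
        assert res.difference == 0.0 and res.p_value == 1.0

    def test_perfect_vs_random_is_significant_at_study_size(self):
        rng = np.random.default_rng(3)
        ids = [f"p{i}" for i in range(99)]
        truth = {pid: i < 43 for i, pid in enumerate(ids)}
        perfect = {pid: 1.0 if truth[pid] else 0.0 for pid in ids}
        noise = {pid: float(x) for pid, x in zip(ids, rng.standard_normal(99))}
        res = compare_auc(perfect, noise, truth, n_bootstrap=200, seed=1)
        assert res.p_value < 0.01
        assert res.bootstrap_ci[0] > 0.0

    def test_null_simulation_keeps_nominal_size(self):
        # independent random markers, 50/50: the paired test should retain
        # p > 0.05 in ~95% of replicates
        rng = np.random.default_rng(11)
        hold = 0
        n_rep = 200
        for _ in range(n_rep):
            ids = [f"p{i}" for i in range(100)]
            truth = {pid: i < 50 for i, pid in enumerate(ids)}
            a = {pid: float(x) for pid, x in zip(ids, rng.standard_normal(100))}
            b = {pid: float(x) for pid, x in zip(ids, rng.standard_normal(100))}
            if compare_auc(a, b, truth, n_bootstrap=0).p_value > 0.05:
                hold += 1
        assert hold / n_rep >= 0.95

    def test_unpaired_input_rejected(self):
        scores, truth = _maps([1, 2], [0])
        other = dict(scores)
        other.pop("d0")
        with pytest.raises(ValueError, match="identical"):
            compare_auc(scores, other, truth)

    def test_bootstrap_ci_is_seed_reproducible(self):
        rng = np.random.default_rng(21)
        scores, truth = _maps(rng.normal(1, 1, 20), rng.normal(0, 1, 20))
        other = {k: v + rng.normal(0, 0.1) for k, v in scores.items()}
        r1 = compare_auc(scores, other, truth, n_bootstrap=100, seed=5)
        r2 = compare_auc(scores, other, truth, n_bootstrap=100, seed=5)
        assert r1.bootstrap_ci == r2.bootstrap_ci
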