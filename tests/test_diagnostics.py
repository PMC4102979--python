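"""Confusion-table metrics: printed-value checks, oracles and invariants."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from romadx import (
    ConfusionTable,
    cohens_kappa,
    diagnostic_accuracy,
    diagnostic_odds,
    evaluate_marker,
    evaluate_table,
    likelihood_ratios,
    make_confusion,
    npv,
    ppv,
    sensitivity,
    specificity,
    wilson_interval,
)

counts = st.integers(min_value=0, max_value=60)


def nonempty_table(tp, fp, fn, tn):
    return tp + fp + fn + tn > 0


class TestMakeConfusion:
    def test_all_negative_benign(self):
        scores = {f"p{i}": 1.0 for i in range(5)}
        truth = {f"p{i}": False for i in range(5)}
        assert make_confusion(scores, truth, 10.0).as_tuple() == (0, 0, 0, 5)

    def test_score_equal_to_cutoff_is_positive(self):
        ct = make_confusion({"a": 22.5}, {"a": True}, 22.5)
        assert ct.tp == 1 and ct.fn == 0

    def test_id_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            make_confusion({"a": 1.0}, {"b": True}, 0.5)

    def test_nonfinite_cutoff_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            make_confusion({"a": 1.0}, {"a": True}, math.inf)


class TestWilsonInterval:
    def test_boundary_cases_pin_to_0_and_100(self):
        lo, hi = wilson_interval(0, 20)
        assert lo == 0.0 and hi < 1.0
        lo, hi = wilson_interval(20, 20)
        assert lo > 0.0 and hi == 1.0

    def test_matches_statsmodels(self):
        # independent library route for the same interval
        from statsmodels.stats.proportion import proportion_confint

        for x, n in [(32, 43), (9, 9), (0, 12), (7, 99), (54, 56)]:
            lo, hi = wilson_interval(x, n)
            slo, shi = proportion_confint(x, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(slo, abs=1e-10)
            assert hi == pytest.approx(shi, abs=1e-10)

    def test_matches_score_test_inversion_all_n_up_to_50(self):
        # brute-force oracle: the Wilson bounds are the roots in p of
        # (phat - p)^2 = z^2 p(1-p)/n, found here by bisection
        z = 1.959963984540054

        def score_stat(p, x, n):
            return (x / n - p) ** 2 - z * z * p * (1 - p) / n

        def bisect(f, a, b):
            for _ in range(200):
                m = (a + b) / 2
                if f(a) * f(m) <= 0:
                    b = m
                else:
                    a = m
            return (a + b) / 2

        for n in range(1, 51):
            for x in range(n + 1):
                lo, hi = wilson_interval(x, n)
                phat = x / n
                if x > 0:
                    oracle_lo = bisect(lambda p: score_stat(p, x, n), 1e-12, phat)
                    assert lo == pytest.approx(oracle_lo, abs=1e-8)
                else:
                    assert lo == 0.0
                if x < n:
                    # start just above phat: p = phat is itself a root when x = 0
                    oracle_hi = bisect(
                        lambda p: -score_stat(p, x, n), max(phat, 1e-12), 1 - 1e-12
                    )
                    assert hi == pytest.approx(oracle_hi, abs=1e-8)
                else:
                    assert hi == 1.0


class TestProportionMetrics:
    def test_roma_total_column(self):
        ct = ConfusionTable(32, 2, 11, 54)
        s = sensitivity(ct)
        assert s.value == pytest.approx(74.4, abs=0.05)
        assert (round(s.ci_low, 2), round(s.ci_high, 2)) == (59.76, 85.07)
        assert specificity(ct).value == pytest.approx(96.4, abs=0.05)
        assert ppv(ct).value == pytest.approx(94.1, abs=0.05)
        assert npv(ct).value == pytest.approx(83.1, abs=0.05)
        assert diagnostic_accuracy(ct).value == pytest.approx(86.9, abs=0.05)

    def test_ca125_ppv_and_perfect_specificity(self):
        assert ppv(ConfusionTable(37, 18, 6, 38)).value == pytest.approx(67.3, abs=0.05)
        sp = specificity(ConfusionTable(19, 0, 3, 9))
        assert sp.value == 100.0
        assert (round(sp.ci_low), round(sp.ci_high)) == (70, 100)

    def test_zero_denominator_tagged_not_raised(self):
        ct = ConfusionTable(0, 3, 0, 7)  # nobody diseased
        s = sensitivity(ct)
        assert not s.defined and math.isnan(s.value)

    @given(tp=counts, fp=counts, fn=counts, tn=counts)
    @settings(max_examples=200, deadline=None)
    def test_prevalence_weighted_accuracy_identity(self, tp, fp, fn, tn):
        if not nonempty_table(tp, fp, fn, tn) or tp + fn == 0 or fp + tn == 0:
            return
        ct = ConfusionTable(tp, fp, fn, tn)
        sens = sensitivity(ct).value
        spec = specificity(ct).value
        da = diagnostic_accuracy(ct).value
        n1, n0 = ct.n_diseased, ct.n_healthy
        assert da == pytest.approx((sens * n1 + spec * n0) / ct.n, abs=1e-10)
        # count bookkeeping is exact
        assert sens * n1 / 100 + ct.fn == pytest.approx(n1, abs=1e-9)


class TestRatioMetrics:
    def test_lr_point_estimates_match_published(self):
        lr_pos, lr_neg = likelihood_ratios(ConfusionTable(32, 2, 11, 54))
        assert lr_pos.value == pytest.approx(20.8, abs=0.05)
        assert lr_neg.value == pytest.approx(0.27, abs=0.005)
        lr_pos, _ = likelihood_ratios(ConfusionTable(37, 18, 6, 38))
        assert lr_pos.value == pytest.approx(2.7, abs=0.05)

    def test_perfect_test_limits(self):
        lr_pos, lr_neg = likelihood_ratios(ConfusionTable(10, 0, 0, 20))
        assert lr_pos.value == math.inf and lr_neg.value == 0.0

    def test_lr_ci_against_parametric_bootstrap(self):
        # oracle: resample the two binomial margins and take percentile CIs;
        # the log-method interval should land close to it
        ct = ConfusionTable(37, 18, 6, 38)
        lr_pos, lr_neg = likelihood_ratios(ct)
        rng = np.random.default_rng(7)
        n1, n0 = ct.n_diseased, ct.n_healthy
        tp = rng.binomial(n1, ct.tp / n1, 4000)
        fp = rng.binomial(n0, ct.fp / n0, 4000)
        keep = fp > 0
        boot = (tp[keep] / n1) / (fp[keep] / n0)
        blo, bhi = np.percentile(boot, [2.5, 97.5])
        assert lr_pos.ci_low < lr_pos.value < lr_pos.ci_high
        for analytic, oracle in [(lr_pos.ci_low, blo), (lr_pos.ci_high, bhi)]:
            assert 0.5 < analytic / oracle < 2.0
        width_ratio = math.log(lr_pos.ci_high / lr_pos.ci_low) / math.log(bhi / blo)
        assert 0.6 < width_ratio < 1.6

    def test_dor_published_columns_and_log_ci(self):
        d = diagnostic_odds(ConfusionTable(32, 2, 11, 54))
        assert d.value == pytest.approx(78.545, abs=1e-3)  # prints as 78.6
        assert (round(d.ci_low, 2), round(d.ci_high, 1)) == (16.36, 377.1)
        d = diagnostic_odds(ConfusionTable(37, 18, 6, 38))
        assert d.value == pytest.approx(13.0, abs=0.05)
        # published CIs round from z = 1.96; the exact quantile shifts the
        # upper bound by ~1 in the fourth significant digit
        assert d.ci_low == pytest.approx(4.653, abs=0.005)
        assert d.ci_high == pytest.approx(36.43, abs=0.02)

    def test_dor_degenerate_and_corrected(self):
        assert diagnostic_odds(ConfusionTable(1, 1, 1, 1)).value == 1.0
        und = diagnostic_odds(ConfusionTable(5, 0, 2, 7))
        assert und.value == math.inf and not und.defined
        corr = diagnostic_odds(ConfusionTable(5, 0, 2, 7), continuity_correction=True)
        assert math.isfinite(corr.value) and corr.defined

    @given(tp=st.integers(1, 40), fp=st.integers(1, 40),
           fn=st.integers(1, 40), tn=st.integers(1, 40))
    @settings(max_examples=200, deadline=None)
    def test_dor_equals_lr_ratio(self, tp, fp, fn, tn):
        ct = ConfusionTable(tp, fp, fn, tn)
        lr_pos, lr_neg = likelihood_ratios(ct)
        assert diagnostic_odds(ct).value == pytest.approx(
            lr_pos.value / lr_neg.value, rel=1e-10
        )


class TestKappa:
    def test_published_point_estimate(self):
        k = cohens_kappa(ConfusionTable(32, 2, 11, 54))
        assert round(k.value, 1) == 0.7
        assert k.value == pytest.approx(0.726, abs=1e-3)

    def test_perfect_and_chance_agreement(self):
        assert cohens_kappa(ConfusionTable(10, 0, 0, 20)).value == pytest.approx(1.0)
        assert cohens_kappa(ConfusionTable(25, 25, 25, 25)).value == pytest.approx(0.0)

    def test_degenerate_margins_tagged(self):
        k = cohens_kappa(ConfusionTable(0, 0, 0, 9))
        assert not k.defined

    @given(tp=counts, fp=counts, fn=counts, tn=counts)
    @settings(max_examples=200, deadline=None)
    def test_invariant_under_class_swap(self, tp, fp, fn, tn):
        if not nonempty_table(tp, fp, fn, tn):
            return
        a = cohens_kappa(ConfusionTable(tp, fp, fn, tn))
        b = cohens_kappa(ConfusionTable(tn, fn, fp, tp))
        if a.defined and b.defined:
            assert a.value == pytest.approx(b.value, abs=1e-12)


class TestEvaluateMarker:
    def test_full_suite_is_serialisable(self):
        scores = {"a": 25.0, "b": 10.0, "c": 30.0, "d": 5.0}
        truth = {"a": True, "b": True, "c": False, "d": False}
        ev = evaluate_marker(scores, truth, 20.0)
        d = ev.to_dict()
        assert d["confusion"] == {"tp": 1, "fp": 1, "fn": 1, "tn": 1}
        assert set(d["metrics"]) == {
            "sensitivity", "specificity", "ppv", "npv", "diagnostic_accuracy",
            "lr_positive", "lr_negative", "diagnostic_odds", "cohens_kappa",
        }

    def test_matches_evaluate_table(self):
        ct = ConfusionTable(16, 0, 6, 9)
        ev = evaluate_table(ct)
        assert ev.metrics["sensitivity"].value == pytest.approx(72.7, abs=0.05)
        assert ev.metrics["specificity"].value == 100.0
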