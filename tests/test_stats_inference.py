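import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tsescore.stats_inference import (
    SeparationError,
    bh_adjust,
    cox_fit,
    delong_test,
    fisher_exact,
    km_fit,
    logistic_fit,
    logrank,
    rank_tests,
    roc_auc,
)


def auc_all_pairs(score, label):
    """Independent oracle: all-pairs concordance with ties counted 1/2."""
    score = np.asarray(score, dtype=float)
    label = np.asarray(label, dtype=int)
    pos = score[label == 1]
    neg = score[label == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def fisher_oracle(a, b, c, d):
    """Independent oracle: exact-fraction hypergeometric enumeration using the
    factorial formula."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    f = math.factorial
    pmfs = {
        k: Fraction(
            f(r1) * f(r2) * f(c1) * f(n - c1),
            f(n) * f(k) * f(r1 - k) * f(c1 - k) * f(r2 - c1 + k),
        )
        for k in range(lo, hi + 1)
    }
    return float(min(Fraction(1), sum(p for p in pmfs.values() if p <= pmfs[a])))


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_constant_score_half(self):
        res = roc_auc([5.0] * 10, [0, 1] * 5)
        assert res.auc == 0.5

    def test_hand_example(self):
        res = roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.auc == 1.0

    def test_matches_all_pairs_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(6, 60))
            score = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            label = rng.binomial(1, 0.5, size=n)
            if label.min() == label.max():
                continue
            assert abs(roc_auc(score, label).auc - auc_all_pairs(score, label)) < 1e-12

    def test_curve_endpoints_and_area(self):
        rng = np.random.default_rng(1)
        score = rng.normal(size=80)
        label = rng.binomial(1, 0.4, size=80)
        res = roc_auc(score, label)
        assert res.fpr[0] == 0.0 and res.tpr[0] == 0.0
        assert res.fpr[-1] == 1.0 and res.tpr[-1] == 1.0
        assert abs(np.trapezoid(res.tpr, res.fpr) - res.auc) < 1e-10

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestDeLong:
    def test_self_comparison(self):
        rng = np.random.default_rng(0)
        score = rng.normal(size=50)
        label = rng.binomial(1, 0.5, size=50)
        auc_a, auc_b, z, p = delong_test(score, score, label)
        assert auc_a == auc_b
        assert z == 0.0 and p == 1.0

    def test_aucs_match_roc_auc(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=60), rng.normal(size=60)
        label = rng.binomial(1, 0.5, size=60)
        auc_a, auc_b, _, _ = delong_test(a, b, label)
        assert auc_a == roc_auc(a, label).auc
        assert auc_b == roc_auc(b, label).auc

    def test_clearly_better_classifier_significant(self):
        rng = np.random.default_rng(2)
        label = np.r_[np.ones(100), np.zeros(100)].astype(int)
        good = label + rng.normal(0, 0.3, 200)
        noise = rng.normal(size=200)
        _, _, _, p = delong_test(good, noise, label)
        assert p < 1e-6

    def test_degenerate_class_sizes_rejected(self):
        with pytest.raises(ValueError):
            delong_test([1, 2, 3], [1, 2, 3], [1, 0, 0])

    def test_null_p_uniform(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(300):
            label = np.r_[np.ones(40), np.zeros(40)].astype(int)
            a = rng.normal(size=80)
            b = rng.normal(size=80)
            pvals.append(delong_test(a, b, label)[3])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestFisher:
    def test_diagonal_table(self):
        _, p = fisher_exact([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10), abs=1e-15)

    def test_no_association(self):
        _, p = fisher_exact([[5, 5], [5, 5]])
        assert p == 1.0

    def test_odds_ratio(self):
        odds, _ = fisher_exact([[8, 2], [1, 5]])
        assert odds == pytest.approx(20.0)

    def test_matches_oracle_small_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 12, size=4)
            p_impl = fisher_exact([[a, b], [c, d]])[1]
            assert abs(p_impl - fisher_oracle(int(a), int(b), int(c), int(d))) < 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[-1, 2], [3, 4]])


class TestRankTests:
    def test_identical_groups(self):
        x = np.arange(20, dtype=float)
        _, p, name = rank_tests([x, x])
        assert name == "wilcoxon-rank-sum"
        assert p > 0.99

    def test_fully_separated(self):
        stat, p, _ = rank_tests([np.arange(10.0), np.arange(100.0, 110.0)])
        assert stat == 0.0  # U statistic at its minimum: no concordant pair
        assert p < 1e-3

    def test_kw_matches_wilcoxon_on_two_groups(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=30), rng.normal(0.5, 1, size=30)
        _, p2, _ = rank_tests([a, b])
        stat3, p3, name = rank_tests([a, b, rng.normal(size=30)])
        assert name == "kruskal-wallis"
        # KW on the same two groups equals the squared-z Wilcoxon
        kw_stat, kw_p, _ = (sps.kruskal(a, b).statistic, sps.kruskal(a, b).pvalue, None)
        assert kw_p == pytest.approx(p2, rel=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_tests([np.array([1.0]), np.array([])])


class TestBHAdjust:
    def test_hand_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.1, 0.1, 0.1]), [0.1, 0.1, 0.1])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_matches_statsmodels_convention(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205]
        expected = [0.008, 0.032, 0.0672, 0.0672, 0.0672, 0.08, 0.0845714285714286, 0.205]
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_order_preserving(self, pvals):
        adj = bh_adjust(pvals)
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestLogisticFit:
    def test_intercept_only_balanced(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        fit = logistic_fit(np.empty((100, 0)), y, add_intercept=True)
        assert fit.loc["intercept", "coef"] == pytest.approx(0.0, abs=1e-8)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(7)
        n = 5000
        x = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-1 + 2 * x))))
        fit = logistic_fit(x, y)
        assert abs(fit.loc["intercept", "coef"] + 1) < 3 * fit.loc["intercept", "se"]
        assert abs(fit.loc["x0", "coef"] - 2) < 3 * fit.loc["x0", "se"]

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=500)
        y = rng.binomial(1, 1 / (1 + np.exp(-x)))
        c1 = logistic_fit(x, y).loc["x0", "coef"]
        c2 = logistic_fit(2 * x, y).loc["x0", "coef"]
        assert c2 == pytest.approx(c1 / 2, rel=1e-6)

    def test_separation_detected(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.raises(SeparationError):
            logistic_fit(x, y)

    def test_rank_deficient_rejected(self):
        x = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="rank"):
            logistic_fit(x, np.r_[np.ones(5), np.zeros(5)])


class TestSurvival:
    def test_km_uncensored_product_limit(self):
        fit = km_fit([1.0, 2.0, 3.0], [1, 1, 1])
        surv = dict(zip(fit.km_times, fit.km_survival))
        assert surv[1.0] == pytest.approx(2 / 3)
        assert surv[2.0] == pytest.approx(1 / 3)
        assert surv[3.0] == pytest.approx(0.0)

    def test_km_equals_empirical_no_censoring(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(1.0, size=100)
        fit = km_fit(times, np.ones(100, dtype=int))
        for t, s in zip(fit.km_times[1:], fit.km_survival[1:]):
            assert s == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_km_monotone_bounded(self):
        rng = np.random.default_rng(10)
        times = rng.exponential(1.0, size=80)
        events = rng.binomial(1, 0.7, size=80)
        fit = km_fit(times, events)
        assert (np.diff(fit.km_survival) <= 1e-12).all()
        assert fit.km_survival.min() >= 0 and fit.km_survival.max() <= 1

    def test_logrank_identical_groups(self):
        times = np.tile(np.arange(1.0, 21.0), 2)
        events = np.ones(40, dtype=int)
        groups = np.r_[np.zeros(20), np.ones(20)]
        _, p = logrank(times, events, groups)
        assert p > 0.95

    def test_logrank_separated_groups(self):
        rng = np.random.default_rng(11)
        t1 = rng.exponential(1.0, 50)
        t2 = rng.exponential(5.0, 50)
        _, p = logrank(np.r_[t1, t2], np.ones(100, dtype=int), np.r_[np.zeros(50), np.ones(50)])
        assert p < 1e-4

    def test_logrank_all_censored_rejected(self):
        with pytest.raises(ValueError, match="censored"):
            logrank([1.0, 2.0], [0, 0], [0, 1])

    def test_cox_recovers_hr(self):
        rng = np.random.default_rng(12)
        n = 2000
        g = rng.binomial(1, 0.5, n).astype(float)
        latent = rng.exponential(1 / (0.1 * np.exp(np.log(2) * g)))
        censor = rng.exponential(30.0, n)
        fit = cox_fit(np.minimum(latent, censor), (latent <= censor).astype(int), g)
        assert abs(fit.iloc[0]["coef"] - np.log(2)) < 3 * fit.iloc[0]["se"]

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_fit([0.0, 1.0], [1, 1])
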