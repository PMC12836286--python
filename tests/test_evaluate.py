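"""Metrics, intervals and statistical tests."""

import math

import numpy as np
import pytest
from scipy import stats

import _oracles as oracles
from noderad.core import ValidationError
from noderad.evaluate import (
    _bca_interval,
    bca_bootstrap_auc_ci,
    clopper_pearson,
    confusion_metrics,
    delong_test,
    paired_correctness_test,
    roc_auc,
    roc_curve_points,
)


class TestConfusion:
    def test_direct_arithmetic(self):
        # TP=2, FN=1, TN=3, FP=1
        labels = [1, 1, 1, 0, 0, 0, 0]
        scores = [0.9, 0.8, 0.1, 0.7, 0.2, 0.3, 0.1]
        m = confusion_metrics(np.array(labels), np.array(scores), 0.5)
        assert m["SEN"] == pytest.approx(2 / 3)
        assert m["SPE"] == pytest.approx(3 / 4)
        assert m["ACC"] == pytest.approx(5 / 7)
        assert m["PPV"] == pytest.approx(2 / 3)
        assert m["NPV"] == pytest.approx(3 / 4)

    def test_all_negative_gives_undefined_ppv(self):
        m = confusion_metrics(np.array([0, 1]), np.array([0.1, 0.2]), 0.5)
        assert math.isnan(m["PPV"])

    def test_perfect_predictions(self):
        m = confusion_metrics(np.array([0, 1, 1]), np.array([0.1, 0.9, 0.8]), 0.5)
        assert all(m[k] == 1 for k in ("SEN", "SPE", "ACC", "PPV", "NPV"))


class TestAuc:
    def test_perfect_ranking(self):
        assert roc_auc(np.array([0, 1]), np.array([0.2, 0.8])) == 1.0

    def test_all_ties(self):
        assert roc_auc(np.array([0, 1, 0, 1]), np.full(4, 0.5)) == 0.5

    def test_enumerated_pairs(self):
        assert roc_auc(np.array([1, 1, 0, 0]), np.array([0.9, 0.4, 0.6, 0.1])) == 0.75

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc(np.array([1, 1]), np.array([0.1, 0.2]))

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        labels = (rng.random(50) < 0.3).astype(int)
        labels[:2] = [0, 1]
        scores = np.round(rng.random(50), 2)  # force some ties
        fpr, tpr, _ = roc_curve_points(labels, scores)
        assert np.trapezoid(tpr, fpr) == pytest.approx(roc_auc(labels, scores))


class TestClopperPearson:
    def test_zero_successes_closed_form(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10))

    def test_all_successes_boundary(self):
        lo, hi = clopper_pearson(10, 10)
        assert hi == 1
        assert lo == pytest.approx(0.025 ** (1 / 10))

    def test_invalid_level(self):
        with pytest.raises(ValidationError):
            clopper_pearson(1, 2, level=1.5)

    def test_coverage_at_least_nominal(self):
        """Exact interval covers p in >= 95% of 2000 simulated binomials."""
        n, p = 50, 0.2
        rng = np.random.default_rng(99)
        xs = rng.binomial(n, p, 2000)
        intervals = {x: clopper_pearson(x, n) for x in np.unique(xs)}
        cover = np.mean([intervals[x][0] <= p <= intervals[x][1] for x in xs])
        se = math.sqrt(0.95 * 0.05 / 2000)
        assert cover >= 0.95 - 3 * se


class TestBcaBootstrap:
    def test_degenerate_distribution_collapses(self):
        labels = np.array([0] * 5 + [1] * 5)
        scores = np.where(labels == 1, 0.9, 0.1)  # AUC 1 in every resample
        lo, hi = bca_bootstrap_auc_ci(labels, scores, n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_zero_corrections_reduce_to_percentile(self):
        boot = np.random.default_rng(1).normal(0.8, 0.05, 1000)
        lo, hi = _bca_interval(boot, z0=0.0, a=0.0, level=0.95)
        assert lo == pytest.approx(np.quantile(boot, 0.025))
        assert hi == pytest.approx(np.quantile(boot, 0.975))

    def test_matches_straightforward_reimplementation(self):
        """Same seed and resampling order => identical interval."""
        rng = np.random.default_rng(77)
        labels = (rng.random(60) < 0.4).astype(int)
        labels[:2] = [0, 1]
        scores = np.clip(labels * 0.4 + rng.random(60) * 0.6, 0, 1)
        got = bca_bootstrap_auc_ci(labels, scores, n_boot=500, seed=13)

        def slow_auc(lab, sc):
            pos = sc[lab == 1]
            neg = sc[lab == 0]
            wins = sum(
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            )
            return wins / (len(pos) * len(neg))

        n = len(labels)
        theta = slow_auc(labels, scores)
        r = np.random.default_rng(np.random.PCG64(13))
        boot = []
        for _ in range(500):
            while True:
                idx = r.integers(0, n, n)
                if 0 < labels[idx].sum() < n:
                    break
            boot.append(slow_auc(labels[idx], scores[idx]))
        boot = np.array(boot)
        prop = min(max(np.mean(boot < theta), 1 / 1000), 1 - 1 / 1000)
        z0 = stats.norm.ppf(prop)
        jack = []
        for i in range(n):
            keep = np.ones(n, bool)
            keep[i] = False
            jack.append(slow_auc(labels[keep], scores[keep]))
        jack = np.array(jack)
        d = jack.mean() - jack
        a = (d**3).sum() / (6 * (d**2).sum() ** 1.5)
        expect = []
        for q in (0.025, 0.975):
            zq = stats.norm.ppf(q)
            adj = z0 + (z0 + zq) / (1 - a * (z0 + zq))
            expect.append(np.quantile(boot, stats.norm.cdf(adj)))
        assert got[0] == pytest.approx(expect[0], abs=1e-12)
        assert got[1] == pytest.approx(expect[1], abs=1e-12)


class TestDelong:
    def test_identical_scores(self):
        labels = np.array([0, 1, 0, 1, 1])
        s = np.array([0.1, 0.9, 0.3, 0.8, 0.7])
        out = delong_test(labels, s, s)
        assert out["p"] == 1.0
        assert out["auc_a"] == out["auc_b"]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_placement_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = int(rng.integers(8, 31))
        labels = (rng.random(n) < 0.5).astype(int)
        labels[:4] = [0, 0, 1, 1]
        sa = rng.random(n)
        sb = np.round(rng.random(n), 1)
        got = delong_test(labels, sa, sb)
        auc_a, auc_b, z, p = oracles.delong_oracle(labels, sa, sb)
        assert got["auc_a"] == pytest.approx(auc_a, abs=1e-12)
        assert got["auc_b"] == pytest.approx(auc_b, abs=1e-12)
        assert got["p"] == pytest.approx(p, abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(14)
        labels = (rng.random(40) < 0.4).astype(int)
        labels[:2] = [0, 1]
        sa, sb = rng.random(40), rng.random(40)
        p1 = delong_test(labels, sa, sb)["p"]
        p2 = delong_test(labels, np.exp(3 * sa), sb**3)["p"]
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_degenerate_perfect_separation_flagged(self):
        labels = np.array([0, 0, 1, 1])
        sa = np.array([0.1, 0.2, 0.8, 0.9])  # perfect, zero variance
        sb = np.array([0.5, 0.5, 0.5, 0.5])
        out = delong_test(labels, sa, sb)
        assert math.isnan(out["p"])  # flagged, not p = 0

    def test_variance_nonnegative(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            labels = (rng.random(20) < 0.5).astype(int)
            labels[:4] = [0, 0, 1, 1]
            out = delong_test(labels, rng.random(20), rng.random(20))
            assert out["var"] >= 0


class TestPairedCorrectness:
    def test_identical_vectors(self):
        assert paired_correctness_test(np.ones(5), np.ones(5))["p"] == 1.0

    def test_closed_form_on_ten_elements(self):
        a = np.array([1, 1, 1, 0, 1, 1, 0, 1, 1, 1], float)
        b = np.array([1, 0, 1, 0, 0, 1, 1, 1, 0, 1], float)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p = 2 * stats.t.sf(abs(t), len(d) - 1)
        out = paired_correctness_test(a, b)
        assert out["t"] == pytest.approx(t)
        assert out["p"] == pytest.approx(p)

    def test_complementary_vectors_degenerate(self):
        out = paired_correctness_test(np.ones(6), np.zeros(6))
        assert out["p"] == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            paired_correctness_test(np.ones(3), np.ones(4))
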