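"""ROC curves, rank AUC, Hanley-McNeil SE, z-tests, DeLong comparison."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vcbench.errors import VcbenchError
from vcbench.roc import (
    ScoredCall,
    auc_rank,
    auc_se,
    auc_test,
    compare_auc,
    roc_curve,
    scored_calls,
)
from vcbench.benchmark import BenchmarkSets
from vcbench.vcfio import VariantKey


def calls_from(pos_scores, neg_scores):
    out = []
    for i, s in enumerate(pos_scores):
        out.append(ScoredCall(VariantKey("1", i + 1, "A", "G"), float(s), True))
    for i, s in enumerate(neg_scores):
        out.append(ScoredCall(VariantKey("1", i + 1001, "A", "G"), float(s), False))
    return out


def brute_force_auc(calls):
    """O(n^2) positive-negative pair count, ties worth 1/2."""
    pos = [c.score for c in calls if c.label]
    neg = [c.score for c in calls if not c.label]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation(self):
        res = roc_curve(calls_from([3, 4], [1, 2]))
        assert res.auc == 1.0
        assert res.points[0] == (0.0, 0.0)
        assert res.points[-1] == (1.0, 1.0)
        assert (0.0, 1.0) in res.points
        assert res.se == 0.0

    def test_interleaved_scores_give_half(self):
        # labels independent of scores by symmetric interleaving
        res = roc_curve(calls_from([1, 3, 6, 8], [2, 4, 5, 7]))
        assert res.auc == 0.5

    def test_single_class_raises_naming_missing_class(self):
        with pytest.raises(VcbenchError, match="negative"):
            roc_curve(calls_from([1, 2], []))
        with pytest.raises(VcbenchError, match="positive"):
            roc_curve(calls_from([], [1, 2]))

    def test_rank_auc_equals_trapezoid_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 41))
            scores = rng.choice(np.arange(20), size=n)  # heavy ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            calls = [
                ScoredCall(VariantKey("1", i + 1, "A", "G"), float(s), bool(l))
                for i, (s, l) in enumerate(zip(scores, labels))
            ]
            res = roc_curve(calls)
            assert res.auc == pytest.approx(
                float(np.trapezoid(res.tpr, res.fpr)), abs=1e-12
            )


class TestAucRank:
    @pytest.mark.parametrize(
        "pos,neg,expected",
        [([2], [1], 1.0), ([1], [1], 0.5), ([1], [2], 0.0)],
    )
    def test_tiny_cases(self, pos, neg, expected):
        assert auc_rank(calls_from(pos, neg)) == expected

    def test_matches_brute_force_pair_count(self, rng):
        for _ in range(10):
            calls = calls_from(
                rng.integers(0, 15, size=int(rng.integers(3, 16))),
                rng.integers(0, 15, size=int(rng.integers(3, 16))),
            )
            assert auc_rank(calls) == pytest.approx(brute_force_auc(calls), abs=1e-12)

    def test_negating_scores_and_flipping_labels_preserves_auc(self, rng):
        calls = calls_from(rng.normal(1, 1, 20), rng.normal(0, 1, 20))
        flipped = [ScoredCall(c.key, -c.score, not c.label) for c in calls]
        assert auc_rank(flipped) == pytest.approx(auc_rank(calls), abs=1e-12)


class TestAucSe:
    def test_half_auc_reduces_to_mann_whitney_null_sd(self):
        # closed form: Var = (m + n + 1) / (12 m n) at AUC = 0.5
        for m, n in [(100, 100), (10, 30)]:
            assert auc_se(0.5, m, n) == pytest.approx(
                math.sqrt((m + n + 1) / (12 * m * n)), abs=1e-15
            )

    def test_perfect_auc_has_zero_se(self):
        assert auc_se(1.0, 20, 30) == 0.0

    def test_decreases_with_sample_size(self):
        ses = [auc_se(0.8, n, n) for n in (10, 50, 200, 1000)]
        assert ses == sorted(ses, reverse=True)


class TestAucTest:
    def test_null_auc_gives_p_one(self):
        assert auc_test(0.5, 0.05) == (0.0, 1.0)

    def test_z_five(self):
        z, p = auc_test(0.75, 0.05)
        assert z == pytest.approx(5.0)
        assert p == pytest.approx(5.733e-7, rel=1e-3)

    def test_zero_se_degenerate(self):
        z, p = auc_test(1.0, 0.0)
        assert math.isinf(z) and p == 0.0


class TestCompareAuc:
    def test_identical_results_not_different(self, rng):
        calls = calls_from(rng.normal(1, 1, 30), rng.normal(0, 1, 30))
        res = roc_curve(calls)
        assert compare_auc(res, res, paired=False) == (0.0, 1.0)
        z, p = compare_auc(res, res, paired=True)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self, rng):
        a = roc_curve(calls_from(rng.normal(2, 1, 25), rng.normal(0, 1, 25)))
        b = roc_curve(calls_from(rng.normal(1, 1, 25), rng.normal(0, 1, 25)))
        za, _ = compare_auc(a, b)
        zb, _ = compare_auc(b, a)
        assert za == pytest.approx(-zb, abs=1e-12)

    def test_paired_requires_shared_keys(self, rng):
        a = roc_curve(calls_from([3, 4], [1, 2]))
        shifted = [
            ScoredCall(VariantKey("2", c.key.pos, "A", "G"), c.score, c.label)
            for c in a.calls
        ]
        b = roc_curve(shifted)
        with pytest.raises(VcbenchError, match="shared"):
            compare_auc(a, b, paired=True)

    def test_paired_detects_planted_difference(self, rng):
        # same variants, one caller scores informatively, the other barely
        keys = [VariantKey("1", i + 1, "A", "G") for i in range(200)]
        labels = np.arange(200) < 100
        strong = rng.normal(0, 1, 200) + 2.5 * labels
        weak = rng.normal(0, 1, 200) + 0.3 * labels
        a = roc_curve([ScoredCall(k, float(s), bool(l)) for k, s, l in zip(keys, strong, labels)])
        b = roc_curve([ScoredCall(k, float(s), bool(l)) for k, s, l in zip(keys, weak, labels)])
        z, p = compare_auc(a, b, paired=True)
        assert z > 0 and p < 1e-6

    def test_known_separation_detected_in_most_replicates(self):
        # two pipelines with distinct discrimination at n=200 calls each:
        # the unpaired AUC comparison should reject at 5% in >= 90/100 runs
        rng = np.random.default_rng(12345)
        hits = 0
        for _ in range(100):
            a = roc_curve(calls_from(rng.normal(2.0, 1, 100), rng.normal(0, 1, 100)))
            b = roc_curve(calls_from(rng.normal(0.5, 1, 100), rng.normal(0, 1, 100)))
            _, p = compare_auc(a, b)
            hits += p < 0.05
        assert hits >= 90


class TestScoredCalls:
    def test_labels_are_truth_membership_and_scores_qual(self):
        a = frozenset({VariantKey("1", 1, "A", "G")})
        b = frozenset({VariantKey("1", 1, "A", "G"), VariantKey("1", 2, "C", "T")})
        sets = BenchmarkSets(a=a, b=b, c=b)
        scores = {k: float(k.pos * 10) for k in b}
        calls = scored_calls(sets, scores)
        assert [(c.key.pos, c.score, c.label) for c in calls] == [
            (1, 10.0, True),
            (2, 20.0, False),
        ]

    def test_missing_score_raises(self):
        b = frozenset({VariantKey("1", 2, "C", "T")})
        sets = BenchmarkSets(a=frozenset(), b=b, c=b)
        with pytest.raises(VcbenchError, match="no score"):
            scored_calls(sets, {})
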