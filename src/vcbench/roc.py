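"""ROC analysis of caller quality scores against truth-set membership.

A *scored call* is an assessed query call (an element of set B) with the
caller's quality score (typically QUAL) and a binary label: concordant
with the gold standard (``key in A``) or not.  Sweeping thresholds over
the scores yields a ROC curve; its area (AUC) equals the Mann–Whitney
probability that a random concordant call outscores a random discordant
one (ties credited 1/2).

Significance machinery:

* single curve — Hanley–McNeil standard error of the AUC,
  ``SE² = [A(1−A) + (m−1)(Q1−A²) + (n−1)(Q2−A²)] / (mn)`` with
  ``Q1 = A/(2−A)``, ``Q2 = 2A²/(1+A)``, followed by a two-sided normal
  z-test against a null AUC (default 0.5);
* unpaired comparison of two curves — z on the AUC difference with pooled
  Hanley–McNeil errors;
* paired comparison — DeLong's covariance estimator on the calls the two
  pipelines share, which respects the correlation induced by scoring the
  same variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .benchmark import BenchmarkSets, key_sort_key
from .errors import VcbenchError
from .vcfio import VariantKey, VariantRecord, to_keys

__all__ = [
    "ScoredCall",
    "RocResult",
    "roc_curve",
    "auc_rank",
    "auc_se",
    "auc_test",
    "compare_auc",
    "scored_calls",
    "scores_from_records",
]


class ScoredCall(NamedTuple):
    key: VariantKey
    score: float
    label: bool  # True = concordant with the gold standard


@dataclass(frozen=True)
class RocResult:
    """ROC points plus AUC and its significance against a null AUC of 0.5."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    se: float
    z: float
    p: float
    n_pos: int
    n_neg: int
    calls: Tuple[ScoredCall, ...] = field(repr=False, default=())

    @property
    def points(self) -> List[Tuple[float, float]]:
        """(FPR, TPR) pairs from (0,0) to (1,1)."""
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def _split_scores(calls: Sequence[ScoredCall]) -> Tuple[np.ndarray, np.ndarray]:
    pos = np.array([c.score for c in calls if c.label], dtype=float)
    neg = np.array([c.score for c in calls if not c.label], dtype=float)
    if len(pos) == 0:
        raise VcbenchError("ROC undefined: no positive (concordant) calls")
    if len(neg) == 0:
        raise VcbenchError("ROC undefined: no negative (discordant) calls")
    if not (np.isfinite(pos).all() and np.isfinite(neg).all()):
        raise VcbenchError("ROC scores must be finite")
    return pos, neg


def auc_rank(calls: Sequence[ScoredCall]) -> float:
    """Rank (Mann–Whitney) AUC with ties counted half.

    Equals the trapezoidal area under the ROC curve built from the same
    calls — an identity the test suite checks on every instance.
    """
    pos, neg = _split_scores(calls)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def roc_curve(calls: Sequence[ScoredCall]) -> RocResult:
    """Full ROC analysis: points, AUC, Hanley–McNeil SE, z and p vs AUC=0.5.

    Thresholds sweep the distinct scores in descending order with tied
    scores grouped at one threshold; the curve runs from (0,0) to (1,1).
    """
    pos, neg = _split_scores(calls)
    labels = np.array([c.label for c in calls], dtype=int)
    scores = np.array([c.score for c in calls], dtype=float)
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = auc_rank(calls)
    se = auc_se(auc, len(pos), len(neg))
    z, p = auc_test(auc, se)
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        se=se,
        z=z,
        p=p,
        n_pos=len(pos),
        n_neg=len(neg),
        calls=tuple(calls),
    )


def auc_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley–McNeil standard error of an AUC estimate.

    At AUC = 0.5 this reduces to the exact Mann–Whitney null standard
    deviation sqrt((m+n+1)/(12mn)); at AUC = 1 it is 0.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one call in each class")
    a = float(auc)
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (
        a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def auc_test(auc: float, se: float, null_auc: float = 0.5) -> Tuple[float, float]:
    """Two-sided normal z-test of an AUC against a null value."""
    if se <= 0:
        if auc == null_auc:
            return 0.0, 1.0
        return math.copysign(math.inf, auc - null_auc), 0.0
    z = (auc - null_auc) / se
    return z, float(2 * norm.sf(abs(z)))


def _delong_structurals(pos: np.ndarray, neg: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Placement values V10 (per positive) and V01 (per negative)."""
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)


def compare_auc(
    a: RocResult, b: RocResult, paired: bool = False
) -> Tuple[float, float]:
    """Test the AUC difference between two pipelines; returns (z, p).

    Unpaired: z = (AUC_a − AUC_b) / sqrt(SE_a² + SE_b²).  Paired: DeLong
    covariance on the calls whose keys both pipelines share (labels must
    agree on shared keys); raises if no keys are shared.
    """
    if not paired:
        denom = math.hypot(a.se, b.se)
        if denom == 0:
            return (0.0, 1.0) if a.auc == b.auc else (
                math.copysign(math.inf, a.auc - b.auc),
                0.0,
            )
        z = (a.auc - b.auc) / denom
        return z, float(2 * norm.sf(abs(z)))

    score_a = {c.key: c for c in a.calls}
    score_b = {c.key: c for c in b.calls}
    shared = [k for k in score_a if k in score_b]
    if not shared:
        raise VcbenchError("paired comparison impossible: no shared call keys")
    for k in shared:
        if score_a[k].label != score_b[k].label:
            raise VcbenchError(f"shared call {k} has conflicting labels")
    shared.sort(key=key_sort_key)
    labels = np.array([score_a[k].label for k in shared], dtype=bool)
    xa = np.array([score_a[k].score for k in shared], dtype=float)
    xb = np.array([score_b[k].score for k in shared], dtype=float)
    m = int(labels.sum())
    n = int((~labels).sum())
    if m == 0 or n == 0:
        raise VcbenchError("paired comparison needs both classes among shared calls")
    v10a, v01a = _delong_structurals(xa[labels], xa[~labels])
    v10b, v01b = _delong_structurals(xb[labels], xb[~labels])
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())

    def _cov(x, y):
        if len(x) < 2:
            return 0.0
        return float(np.cov(x, y, ddof=1)[0, 1])

    var = (
        _cov(v10a, v10a) + _cov(v10b, v10b) - 2 * _cov(v10a, v10b)
    ) / m + (_cov(v01a, v01a) + _cov(v01b, v01b) - 2 * _cov(v01a, v01b)) / n
    if var <= 0:
        return (0.0, 1.0) if auc_a == auc_b else (
            math.copysign(math.inf, auc_a - auc_b),
            0.0,
        )
    z = (auc_a - auc_b) / math.sqrt(var)
    return z, float(2 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# building scored calls from a benchmark
# ---------------------------------------------------------------------------


def scores_from_records(
    records: Iterable[VariantRecord], snp_only: bool = True
) -> Dict[VariantKey, float]:
    """Map each key of a call set to its record's QUAL (first occurrence wins)."""
    out: Dict[VariantKey, float] = {}
    for rec in records:
        if rec.qual is None:
            continue
        for key in to_keys(rec, snp_only=snp_only):
            out.setdefault(key, float(rec.qual))
    return out


def scored_calls(
    sets: BenchmarkSets, scores: Mapping[VariantKey, float]
) -> List[ScoredCall]:
    """Label every assessed call (set B) by truth-set membership (key ∈ A).

    This is the default construction behind the ROC analysis: positives
    are concordant calls, negatives are calls absent from the gold
    standard; the score is the caller's QUAL.  Both choices are explicit
    arguments so alternatives can be swapped in.
    """
    calls = []
    for key in sorted(sets.b, key=key_sort_key):
        if key not in scores:
            raise VcbenchError(f"no score for assessed call {key}")
        calls.append(ScoredCall(key=key, score=float(scores[key]), label=key in sets.a))
    return calls
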