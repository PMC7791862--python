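"""Continuous benchmarking metrics and call-set summary statistics.

Ratios with zero denominators raise :class:`UndefinedMetricError`; report
writers render them as ``NA`` — never 0 or 1, so degenerate inputs stay
honest.  Internal computation is unrounded; F1 is the harmonic mean of the
*unrounded* precision and recall.  Report rounding (3 d.p. for
recall/precision/Frac_NA/F1, 5 for Ts/Tv, 4 for missense/silent) lives in
:mod:`vcbench.report`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .benchmark import DiscreteCounts
from .errors import UndefinedMetricError
from .intervals import chrom_sort_key
from .vcfio import VariantKey, VariantRecord

__all__ = [
    "ContinuousMetrics",
    "SummaryStats",
    "recall",
    "precision",
    "frac_na",
    "f1",
    "continuous_metrics",
    "tstv",
    "functional_class",
    "per_chromosome_counts",
    "variant_rate",
    "summarize",
    "GRCH37_SPAN",
]

#: Sum of GRCh37 primary-chromosome lengths (1-22, X, Y), in bases.  Default
#: reference span for the variant-rate denominator; configurable because a
#: panel study may prefer its capture footprint instead.
GRCH37_SPAN = 3_095_677_412


def recall(tp: int, fn: int) -> float:
    """TP / (TP + FN): the fraction of assessable truth variants recovered."""
    if tp + fn == 0:
        raise UndefinedMetricError("recall undefined: TP + FN = 0")
    return tp / (tp + fn)


def precision(tp: int, fp: int) -> float:
    """TP / (TP + FP): the fraction of assessable calls that are true."""
    if tp + fp == 0:
        raise UndefinedMetricError("precision undefined: TP + FP = 0")
    return tp / (tp + fp)


def frac_na(nac: int, total_variants: int) -> float:
    """NAC / total calls — the share of the query that could not be judged."""
    if total_variants == 0:
        raise UndefinedMetricError("Frac_NA undefined: no calls")
    return nac / total_variants


def f1(precision_value: float, recall_value: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision_value + recall_value == 0:
        raise UndefinedMetricError("F1 undefined: precision + recall = 0")
    return 2 * precision_value * recall_value / (precision_value + recall_value)


@dataclass(frozen=True)
class ContinuousMetrics:
    """Recall, precision, Frac_NA, F1; ``None`` marks an undefined metric."""

    recall: Optional[float]
    precision: Optional[float]
    frac_na: Optional[float]
    f1: Optional[float]

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "frac_na": self.frac_na,
            "f1": self.f1,
        }


def _maybe(fn, *args) -> Optional[float]:
    try:
        return fn(*args)
    except UndefinedMetricError:
        return None


def continuous_metrics(counts: DiscreteCounts) -> ContinuousMetrics:
    """All four ratio metrics from one category tally (total calls = |B|)."""
    r = _maybe(recall, counts.tp, counts.fn)
    p = _maybe(precision, counts.tp, counts.fp)
    na = _maybe(frac_na, counts.nac, counts.total_calls)
    f = f1(p, r) if (p is not None and r is not None and p + r > 0) else None
    return ContinuousMetrics(recall=r, precision=p, frac_na=na, f1=f)


# ---------------------------------------------------------------------------
# summary statistics (Ts/Tv, functional classes, per-chromosome, rate)
# ---------------------------------------------------------------------------

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}

_MISSENSE_LABELS = {"missense", "missense_variant", "non_synonymous", "nonsynonymous"}
_SILENT_LABELS = {"silent", "synonymous", "synonymous_variant"}


def tstv(keys: Iterable[VariantKey]) -> Tuple[int, int, Optional[float]]:
    """Count transitions (A<->G, C<->T) and transversions; return (ts, tv, ratio).

    Only single-base A/C/G/T substitutions are classifiable; anything else
    is ignored.  The ratio is ``None`` when there are no transversions.
    """
    ts = tv = 0
    for k in keys:
        if len(k.ref) != 1 or len(k.alt) != 1 or k.ref == k.alt:
            continue
        pair = frozenset((k.ref, k.alt))
        if not pair <= set("ACGT"):
            continue
        if pair in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    return ts, tv, (ts / tv if tv else None)


def functional_class(
    records: Iterable[VariantRecord],
) -> Tuple[int, int, Optional[float]]:
    """Transcript-level missense and silent annotation counts and their ratio.

    Every (gene, transcript, effect) entry counts once, so totals can exceed
    the number of variants — one variant may hit several transcripts.
    Labels other than missense/silent are ignored by the ratio.
    """
    missense = silent = 0
    for rec in records:
        for _, _, effect in rec.effects:
            label = effect.strip().lower()
            if label in _MISSENSE_LABELS:
                missense += 1
            elif label in _SILENT_LABELS:
                silent += 1
    return missense, silent, (missense / silent if silent else None)


def per_chromosome_counts(keys: Iterable[VariantKey]) -> Dict[str, int]:
    """Variant count per chromosome, in natural chromosome order."""
    tally: Dict[str, int] = {}
    for k in keys:
        tally[k.chrom] = tally.get(k.chrom, 0) + 1
    return dict(sorted(tally.items(), key=lambda kv: chrom_sort_key(kv[0])))


def variant_rate(n_variants: int, reference_span: int = GRCH37_SPAN) -> int:
    """Denominator d of the "one variant per d bases" rate: round(span / n)."""
    if n_variants <= 0:
        raise UndefinedMetricError("variant rate undefined: no variants")
    return round(reference_span / n_variants)


@dataclass(frozen=True)
class SummaryStats:
    """Call-set level summary: SNP count, Ts/Tv, functional classes, rate."""

    n_snp: int
    ts: int
    tv: int
    tstv_ratio: Optional[float]
    missense: int
    silent: int
    missense_silent_ratio: Optional[float]
    per_chrom: Mapping[str, int]
    variant_rate_denominator: Optional[int]


def summarize(
    records: List[VariantRecord],
    snp_only: bool = True,
    reference_span: int = GRCH37_SPAN,
) -> SummaryStats:
    """General per-caller statistics over a (filtered) call set."""
    from .vcfio import records_to_keys

    keys = records_to_keys(records, snp_only=snp_only)
    ts, tv, ratio = tstv(keys)
    mis, sil, ms_ratio = functional_class(records)
    return SummaryStats(
        n_snp=len(keys),
        ts=ts,
        tv=tv,
        tstv_ratio=ratio,
        missense=mis,
        silent=sil,
        missense_silent_ratio=ms_ratio,
        per_chrom=per_chromosome_counts(keys),
        variant_rate_denominator=(
            variant_rate(len(keys), reference_span) if keys else None
        ),
    )
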