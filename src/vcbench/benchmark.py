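"""The set-theory benchmarking core.

Three sets of variant keys are built from a truth call set, a query call
set, and two region sets:

* ``A`` — truth variants inside the target (capture) regions,
* ``B`` — query variants inside the target regions,
* ``C`` — query variants inside the high-confidence regions.

Six pairwise-disjoint categories then follow by plain set algebra::

    TP  = A ∩ B              concordant calls
    FP  = (B ∩ C) \\ A        assessable calls absent from the truth set
    FN  = (A ∩ C) \\ B        truth calls assessable but missed
    NAC = B \\ (A ∪ C)        calls outside truth and confident regions
    O   = C \\ (A ∪ B)        confident-region calls outside the target
    I   = A \\ (B ∪ C)        truth calls outside confident regions, missed

True negatives are deliberately not computed: without an enumerable
universe of non-variant positions they are not interpretable for a
targeted panel.  Note one structural consequence of the definitions:
membership in both A and C forces membership in B, so FN is empty for
every input at allele-level matching (a property the tests assert).

Matching is allele-level on ``(chrom, pos, ref, alt)`` by default; a
genotype-aware mode is available upstream (see
:func:`vcbench.vcfio.to_keys`) by building the key sets with
``genotype_match=True`` — the algebra here is agnostic to the key type.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Tuple

from .errors import VcbenchError
from .intervals import RegionSet, chrom_sort_key
from .vcfio import VariantKey

__all__ = [
    "BenchmarkSets",
    "DiscreteCounts",
    "ConcordanceTable",
    "build_sets",
    "compute_discrete",
    "concordance",
    "key_sort_key",
]

CATEGORIES = ("tp", "fp", "fn", "nac", "o", "i")


def key_sort_key(key: VariantKey):
    """Deterministic output order: natural chromosome, pos, ref, alt."""
    return (chrom_sort_key(key.chrom), key.pos, key.ref, key.alt)


@dataclass(frozen=True)
class BenchmarkSets:
    """The three sets A, B, C of variant keys underlying all metrics."""

    a: FrozenSet[VariantKey]
    b: FrozenSet[VariantKey]
    c: FrozenSet[VariantKey]


@dataclass(frozen=True)
class DiscreteCounts:
    """The six category key sets plus their counts.

    The six sets are pairwise disjoint and their union is A ∪ B ∪ C;
    ``validate()`` re-checks the partition identities against the source
    sets and is called on every construction via :func:`compute_discrete`.
    """

    tp_keys: FrozenSet[VariantKey]
    fp_keys: FrozenSet[VariantKey]
    fn_keys: FrozenSet[VariantKey]
    nac_keys: FrozenSet[VariantKey]
    o_keys: FrozenSet[VariantKey]
    i_keys: FrozenSet[VariantKey]

    @property
    def tp(self) -> int:
        return len(self.tp_keys)

    @property
    def fp(self) -> int:
        return len(self.fp_keys)

    @property
    def fn(self) -> int:
        return len(self.fn_keys)

    @property
    def nac(self) -> int:
        return len(self.nac_keys)

    @property
    def o(self) -> int:
        return len(self.o_keys)

    @property
    def i(self) -> int:
        return len(self.i_keys)

    @property
    def total_calls(self) -> int:
        """|B| = TP + FP + NAC — the query's assessable-call total."""
        return self.tp + self.fp + self.nac

    def as_dict(self) -> Dict[str, int]:
        return {c: getattr(self, c) for c in CATEGORIES}

    def keys_of(self, category: str) -> List[VariantKey]:
        """The category's variant list in deterministic order."""
        return sorted(getattr(self, f"{category}_keys"), key=key_sort_key)

    def validate(self, sets: BenchmarkSets) -> None:
        """Assert the partition identities against the source A/B/C sets."""
        cats = [getattr(self, f"{c}_keys") for c in CATEGORIES]
        for x, y in combinations(cats, 2):
            if x & y:
                raise VcbenchError("category sets are not pairwise disjoint")
        universe = sets.a | sets.b | sets.c
        if frozenset().union(*cats) != universe:
            raise VcbenchError("categories do not cover A ∪ B ∪ C")
        if self.tp + self.fp + self.nac != len(sets.b):
            raise VcbenchError("|B| != TP + FP + NAC")
        if self.tp + self.fn + self.i != len(sets.a):
            raise VcbenchError("|A| != TP + FN + I")


def build_sets(
    truth: Iterable[VariantKey],
    query: Iterable[VariantKey],
    target: RegionSet,
    confident: RegionSet,
) -> BenchmarkSets:
    """Restrict truth/query keys to target and confident regions.

    A = truth ∩ target, B = query ∩ target, C = query ∩ confident, all by
    position membership.  A is restricted to the target only — not to the
    confident regions — which is what makes the incongruence category
    ``I = A \\ (B ∪ C)`` informative.  An empty target raises: the
    benchmark is undefined for a targeted design with no target.
    An empty confident set is legal (C = ∅; FP, FN and O all vanish).
    """
    if not target:
        raise VcbenchError("target region set is empty; benchmark undefined")
    truth = list(truth)
    query = list(query)
    return BenchmarkSets(
        a=frozenset(k for k in truth if target.contains(k.chrom, k.pos)),
        b=frozenset(k for k in query if target.contains(k.chrom, k.pos)),
        c=frozenset(k for k in query if confident.contains(k.chrom, k.pos)),
    )


def compute_discrete(sets: BenchmarkSets) -> DiscreteCounts:
    """Derive the six categories from A, B, C by set operations."""
    a, b, c = sets.a, sets.b, sets.c
    counts = DiscreteCounts(
        tp_keys=a & b,
        fp_keys=(b & c) - a,
        fn_keys=(a & c) - b,
        nac_keys=b - (a | c),
        o_keys=c - (a | b),
        i_keys=a - (b | c),
    )
    counts.validate(sets)
    return counts


@dataclass(frozen=True)
class ConcordanceTable:
    """Venn partition of n call sets: one exclusive cell per non-empty subset."""

    names: Tuple[str, ...]
    cells: Mapping[FrozenSet[str], int]
    pairwise: Mapping[Tuple[str, str], int]

    def cell(self, *names: str) -> int:
        """Count of keys in exactly these call sets and no others."""
        return self.cells.get(frozenset(names), 0)

    @property
    def common(self) -> int:
        """Keys shared by every call set (the Venn centre)."""
        return self.cells.get(frozenset(self.names), 0)

    def total(self) -> int:
        return sum(self.cells.values())

    def rows(self) -> List[Tuple[str, int]]:
        """(cell label, count) rows, largest subsets first, for TSV output."""
        ordered = sorted(
            self.cells.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
        )
        return [("&".join(sorted(s)), n) for s, n in ordered]


def concordance(callsets: Mapping[str, Iterable[VariantKey]]) -> ConcordanceTable:
    """Tally every cell of the n-set Venn partition of the given call sets.

    Each key in the union is assigned the signature of call sets containing
    it; cells are exclusive, so they sum to |union|.  Pairwise shared counts
    (|X ∩ Y|, not exclusive) are also reported.
    """
    if len(callsets) < 2:
        raise VcbenchError("concordance requires at least two call sets")
    sets = {name: frozenset(keys) for name, keys in callsets.items()}
    names = tuple(sets)
    cells: Dict[FrozenSet[str], int] = {}
    for key in frozenset().union(*sets.values()):
        sig = frozenset(n for n, s in sets.items() if key in s)
        cells[sig] = cells.get(sig, 0) + 1
    pairwise = {
        (x, y): len(sets[x] & sets[y]) for x, y in combinations(names, 2)
    }
    return ConcordanceTable(names=names, cells=cells, pairwise=pairwise)
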