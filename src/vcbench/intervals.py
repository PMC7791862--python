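"""Genomic interval algebra on normalized region sets.

Coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
VCF positions are 1-based, so membership tests convert with ``pos - 1``;
that conversion lives here and nowhere else.

A :class:`RegionSet` is always kept in normal form — per chromosome, a
sorted list of non-overlapping, non-adjacent intervals — so a given set of
covered bases has exactly one representation and set equality is structural
equality.  Adjacent intervals (``[0,5)`` + ``[5,9)``) merge on construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "Region",
    "RegionSet",
    "intersect",
    "union",
    "difference",
    "total_length",
    "contains",
    "subset_keys",
    "normalize_chrom",
    "chrom_sort_key",
]

_CHR_PREFIX = re.compile(r"^chr", re.IGNORECASE)


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` (any case) so GRCh37 dialects compare equal."""
    return _CHR_PREFIX.sub("", str(name))


def chrom_sort_key(chrom: str) -> Tuple[int, int, str]:
    """Natural chromosome order: 1..22, then X, Y, MT, then others lexically."""
    if chrom.isdigit():
        return (0, int(chrom), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if chrom.upper() in special:
        return (0, special[chrom.upper()], "")
    return (1, 0, chrom)


@dataclass(frozen=True, order=True)
class Region:
    """One half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid region {self.chrom}:[{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start


class RegionSet:
    """Normalized set of genomic intervals (per chromosome, sorted, merged)."""

    __slots__ = ("_chroms",)

    def __init__(self, intervals: Iterable[Tuple[str, int, int]] = ()) -> None:
        per_chrom: dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            chrom = normalize_chrom(chrom)
            start, end = int(start), int(end)
            if start < 0 or start >= end:
                raise ValueError(f"invalid interval {chrom}:[{start},{end})")
            per_chrom.setdefault(chrom, []).append((start, end))
        self._chroms: dict[str, np.ndarray] = {
            c: _merge(pairs) for c, pairs in per_chrom.items() if pairs
        }

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_regions(cls, regions: Iterable[Region]) -> "RegionSet":
        return cls((r.chrom, r.start, r.end) for r in regions)

    @classmethod
    def _from_arrays(cls, chroms: Mapping[str, np.ndarray]) -> "RegionSet":
        out = cls.__new__(cls)
        out._chroms = {c: a for c, a in chroms.items() if len(a)}
        return out

    # -- inspection -----------------------------------------------------------

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._chroms, key=chrom_sort_key)

    def intervals(self) -> List[Region]:
        """All intervals in (natural chromosome, start) order."""
        out: List[Region] = []
        for c in self.chromosomes:
            for s, e in self._chroms[c]:
                out.append(Region(c, int(s), int(e)))
        return out

    def total_length(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._chroms.values()))

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """True iff the 1-based position lies on a covered base."""
        arr = self._chroms.get(normalize_chrom(chrom))
        if arr is None:
            return False
        p = int(pos_1based) - 1
        idx = int(np.searchsorted(arr[:, 0], p, side="right")) - 1
        return bool(idx >= 0 and p < arr[idx, 1])

    def __bool__(self) -> bool:
        return bool(self._chroms)

    def __len__(self) -> int:
        return sum(len(a) for a in self._chroms.values())

    def __iter__(self) -> Iterator[Region]:
        return iter(self.intervals())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        if set(self._chroms) != set(other._chroms):
            return False
        return all(np.array_equal(self._chroms[c], other._chroms[c]) for c in self._chroms)

    def __hash__(self) -> int:  # normal form is canonical
        return hash(tuple((c, a.tobytes()) for c, a in sorted(self._chroms.items())))

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} intervals, {self.total_length()} bp)"

    # -- algebra --------------------------------------------------------------

    def intersect(self, other: "RegionSet") -> "RegionSet":
        out: dict[str, np.ndarray] = {}
        for c in set(self._chroms) & set(other._chroms):
            merged = _intersect_arrays(self._chroms[c], other._chroms[c])
            if len(merged):
                out[c] = merged
        return RegionSet._from_arrays(out)

    def union(self, other: "RegionSet") -> "RegionSet":
        out: dict[str, np.ndarray] = {}
        for c in set(self._chroms) | set(other._chroms):
            pairs = [tuple(p) for p in self._chroms.get(c, np.empty((0, 2), int))]
            pairs += [tuple(p) for p in other._chroms.get(c, np.empty((0, 2), int))]
            out[c] = _merge(pairs)
        return RegionSet._from_arrays(out)

    def difference(self, other: "RegionSet") -> "RegionSet":
        out: dict[str, np.ndarray] = {}
        for c, arr in self._chroms.items():
            sub = other._chroms.get(c)
            res = _difference_arrays(arr, sub) if sub is not None else arr.copy()
            if len(res):
                out[c] = res
        return RegionSet._from_arrays(out)

    # -- I/O ------------------------------------------------------------------

    def write_bed(self, path) -> None:
        """Write as BED3, chromosomes in natural order."""
        with open(path, "w") as fh:
            for r in self.intervals():
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def _merge(pairs: Sequence[Tuple[int, int]]) -> np.ndarray:
    """Sort and merge overlapping or adjacent intervals into normal form."""
    if not len(pairs):
        return np.empty((0, 2), dtype=np.int64)
    arr = np.array(sorted(pairs), dtype=np.int64)
    out: List[List[int]] = [[int(arr[0, 0]), int(arr[0, 1])]]
    for s, e in arr[1:]:
        if s <= out[-1][1]:  # overlap or adjacency
            out[-1][1] = max(out[-1][1], int(e))
        else:
            out.append([int(s), int(e)])
    return np.array(out, dtype=np.int64)


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    i = j = 0
    out: List[Tuple[int, int]] = []
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((int(s), int(e)))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64) if out else np.empty((0, 2), dtype=np.int64)


def _difference_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out: List[Tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = int(s)
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, int(b[k, 0])))
            cur = max(cur, int(b[k, 1]))
            k += 1
        if cur < e:
            out.append((cur, int(e)))
    return np.array(out, dtype=np.int64) if out else np.empty((0, 2), dtype=np.int64)


# -- module-level operation aliases (functional style) ------------------------


def intersect(a: RegionSet, b: RegionSet) -> RegionSet:
    """Bases covered by both ``a`` and ``b``."""
    return a.intersect(b)


def union(a: RegionSet, b: RegionSet) -> RegionSet:
    return a.union(b)


def difference(a: RegionSet, b: RegionSet) -> RegionSet:
    """Bases covered by ``a`` but not ``b``."""
    return a.difference(b)


def total_length(r: RegionSet) -> int:
    """Total covered bases."""
    return r.total_length()


def contains(r: RegionSet, chrom: str, pos_1based: int) -> bool:
    return r.contains(chrom, pos_1based)


def subset_keys(keys: Iterable, r: RegionSet) -> list:
    """Keep keys whose (1-based) position lies in ``r``; order preserved.

    A multi-base variant counts as in-region iff its POS base is covered
    (sufficient for the SNP scope of this package).
    """
    return [k for k in keys if r.contains(k.chrom, k.pos)]
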