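"""Synthetic benchmark fixtures with exactly controlled category counts.

The generator emulates the four inputs of a targeted-sequencing benchmark
— truth VCF, query VCF, capture-target BED, high-confidence BED — by
first laying down blocky random region geometry and then planting each
variant in the zone whose membership signature (in target? in confident?
in truth? in query?) produces exactly the requested category:

====  =========================  =============================
cat   zone (position)            membership
====  =========================  =============================
TP    target ∩ confident         truth and query
FP    target ∩ confident         query only
NAC   target \\ confident         query only
I     target \\ confident         truth only
O     confident \\ target         query only
====  =========================  =============================

FN is requestable only as 0: the category (A∩C)\\B is empty for every
possible input, because membership in A forces the position into the
target and membership in C forces the key into the query — together that
is membership in B.  Requesting fn > 0 raises
:class:`UnsatisfiableFixtureError` explaining this.

Planted QUAL/DP always pass the default filters (QUAL > 20, DP > 10);
optional *decoys* are sub-threshold query calls that must be removed by
the filter stage and never surface in any category.  Everything is
reproducible from the seed: independent child streams (regions, truth,
query, QUAL/DP, decoys) mean adding decoys does not shift earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .benchmark import DiscreteCounts, build_sets, compute_discrete
from .errors import UnsatisfiableFixtureError
from .intervals import RegionSet
from .vcfio import VariantKey, VariantRecord, apply_quality_filters, records_to_keys, write_vcf

__all__ = [
    "CategoryCounts",
    "FixtureSpec",
    "Fixture",
    "TrioFixture",
    "generate",
    "generate_trio",
]

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = ("A", "C", "G", "T")

#: Per-category QUAL (location, scale); concordant calls score higher than
#: discordant ones so ROC fixtures separate, mirroring how callers behave.
DEFAULT_QUAL = {
    "tp": (90.0, 15.0),
    "fp": (45.0, 12.0),
    "nac": (45.0, 12.0),
    "o": (70.0, 12.0),
    "truth": (95.0, 10.0),
}


@dataclass(frozen=True)
class CategoryCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    nac: int = 0
    o: int = 0
    i: int = 0

    def as_dict(self) -> Dict[str, int]:
        return asdict(self)

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if v < 0:
                raise ValueError(f"count {name} must be non-negative")


@dataclass(frozen=True)
class FixtureSpec:
    """Requested category counts plus the genome/region/score geometry.

    Defaults emulate a small capture panel: two 200 kb chromosomes, ~30%
    of each under the capture target, ~55% under high-confidence regions
    (in 1 kb blocks, so all overlap zones occur), transition-biased
    alleles (ts_prob 0.8, i.e. an expected Ts/Tv of 4 as seen on coding
    panels), and well-covered, well-scored calls (DP 20-80).
    """

    counts: CategoryCounts = field(default_factory=CategoryCounts)
    n_chroms: int = 2
    chrom_length: int = 200_000
    target_fraction: float = 0.30
    confident_fraction: float = 0.55
    window: int = 1_000
    qual_distributions: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_QUAL)
    )
    depth_range: Tuple[int, int] = (20, 80)
    n_decoys: int = 0
    ts_prob: float = 0.8
    seed: int = 0
    target_regions: Optional[RegionSet] = None
    confident_regions: Optional[RegionSet] = None


@dataclass(frozen=True)
class Fixture:
    """A generated benchmark bundle plus its ground-truth expectations."""

    spec: FixtureSpec
    truth_records: Tuple[VariantRecord, ...]
    query_records: Tuple[VariantRecord, ...]
    target: RegionSet
    confident: RegionSet
    expected: CategoryCounts
    planted: Mapping[str, Tuple[VariantKey, ...]]

    def recover(self, min_qual: float = 20.0, min_depth: int = 10) -> DiscreteCounts:
        """Run the full pipeline (filter → keys → sets → categories) in memory."""
        truth_keys = records_to_keys(self.truth_records)
        query_keys = records_to_keys(
            apply_quality_filters(self.query_records, min_qual, min_depth)
        )
        sets = build_sets(truth_keys, query_keys, self.target, self.confident)
        return compute_discrete(sets)

    def write(self, outdir) -> Dict[str, Path]:
        """Write truth.vcf, query.vcf, target.bed, confident.bed, manifest.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "truth": outdir / "truth.vcf",
            "query": outdir / "query.vcf",
            "target": outdir / "target.bed",
            "confident": outdir / "confident.bed",
            "manifest": outdir / "manifest.json",
        }
        write_vcf(list(self.truth_records), paths["truth"])
        write_vcf(list(self.query_records), paths["query"])
        self.target.write_bed(paths["target"])
        self.confident.write_bed(paths["confident"])
        manifest = {
            "seed": self.spec.seed,
            "counts_requested": self.spec.counts.as_dict(),
            "counts_expected": self.expected.as_dict(),
            "n_decoys": self.spec.n_decoys,
            "n_chroms": self.spec.n_chroms,
            "chrom_length": self.spec.chrom_length,
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return paths


def _random_blocky_regions(
    rng: np.random.Generator, n_chroms: int, chrom_length: int, window: int, frac: float
) -> RegionSet:
    intervals = []
    for ci in range(1, n_chroms + 1):
        n_windows = chrom_length // window
        mask = rng.random(n_windows) < frac
        for wi in np.flatnonzero(mask):
            intervals.append((str(ci), int(wi) * window, (int(wi) + 1) * window))
    return RegionSet(intervals)


def _sample_positions(
    zone: RegionSet, n: int, rng: np.random.Generator, occupied: set
) -> List[Tuple[str, int]]:
    """Draw n distinct (chrom, 1-based pos) uniformly over the zone's bases."""
    if n == 0:
        return []
    ivs = zone.intervals()
    lens = np.array([len(r) for r in ivs], dtype=np.int64)
    total = int(lens.sum())
    if n > total:
        raise UnsatisfiableFixtureError(
            f"zone has {total} bases but {n} positions requested"
        )
    cum = np.cumsum(lens)
    out: List[Tuple[str, int]] = []
    # rejection-sample against already-occupied bases; deterministic per stream
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n + 1000:
            raise UnsatisfiableFixtureError(
                "could not place all variants without collision; zone too crowded"
            )
        off = int(rng.integers(total))
        idx = int(np.searchsorted(cum, off, side="right"))
        reg = ivs[idx]
        pos0 = off - (int(cum[idx]) - int(lens[idx])) + reg.start
        site = (reg.chrom, pos0 + 1)
        if site in occupied:
            continue
        occupied.add(site)
        out.append(site)
    return out


def _draw_alleles(rng: np.random.Generator, ts_prob: float) -> Tuple[str, str]:
    ref = _BASES[int(rng.integers(4))]
    if rng.random() < ts_prob:
        return ref, _TRANSITION[ref]
    others = [b for b in _BASES if b != ref and b != _TRANSITION[ref]]
    return ref, others[int(rng.integers(2))]


def _qual(rng: np.random.Generator, loc: float, scale: float) -> float:
    # clip above the default QUAL>20 filter so planted calls always survive
    return float(np.clip(rng.normal(loc, scale), 25.0, 5000.0).round(2))


def _depth(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(max(lo, 11), max(hi, max(lo, 11) + 1) + 1))


def _record(chrom, pos, ref, alt, qual, depth) -> VariantRecord:
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alts=(alt,), qual=qual,
        filter_field="PASS", depth=depth, genotype=(0, 1),
    )


def generate(spec: FixtureSpec) -> Fixture:
    """Generate a complete, fully reproducible benchmark fixture.

    Central contract (asserted across the test suite):
    ``compute_discrete(build_sets(...))`` on the generated bundle recovers
    ``spec.counts`` exactly, for every satisfiable spec and any seed.
    """
    c = spec.counts
    if c.fn > 0:
        raise UnsatisfiableFixtureError(
            "fn > 0 is unsatisfiable: FN = (A∩C)\\B is empty for every input — "
            "a key in A (truth, in target) and in C (query, in confident) is "
            "necessarily in B (query, in target); missed truth calls fall in I"
        )
    ss = np.random.SeedSequence(spec.seed)
    r_regions, r_truth, r_query, r_scores, r_decoys = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    target = spec.target_regions or _random_blocky_regions(
        r_regions, spec.n_chroms, spec.chrom_length, spec.window, spec.target_fraction
    )
    confident = spec.confident_regions or _random_blocky_regions(
        r_regions, spec.n_chroms, spec.chrom_length, spec.window, spec.confident_fraction
    )

    zone_tc = target.intersect(confident)
    zone_t_only = target.difference(confident)
    zone_c_only = confident.difference(target)

    needs = [
        ("tp+fp (target ∩ confident)", zone_tc, c.tp + c.fp + spec.n_decoys),
        ("nac+i (target \\ confident)", zone_t_only, c.nac + c.i),
        ("o (confident \\ target)", zone_c_only, c.o),
    ]
    for label, zone, n in needs:
        if n > 0 and zone.total_length() < n:
            raise UnsatisfiableFixtureError(
                f"category class {label!r} needs {n} bases but the region "
                f"geometry offers {zone.total_length()}"
            )
    if not target:
        raise UnsatisfiableFixtureError("generated target region set is empty")

    occupied: set = set()
    qd = dict(DEFAULT_QUAL)
    qd.update(spec.qual_distributions)
    lo, hi = spec.depth_range

    planted: Dict[str, List[VariantKey]] = {k: [] for k in ("tp", "fp", "nac", "o", "i")}
    truth_records: List[VariantRecord] = []
    query_records: List[VariantRecord] = []

    def plant(category: str, zone: RegionSet, n: int, in_truth: bool, in_query: bool,
              pos_rng: np.random.Generator) -> None:
        for chrom, pos in _sample_positions(zone, n, pos_rng, occupied):
            ref, alt = _draw_alleles(pos_rng, spec.ts_prob)
            key = VariantKey(chrom, pos, ref, alt)
            planted[category].append(key)
            if in_query:
                loc, scale = qd[category]
                query_records.append(
                    _record(chrom, pos, ref, alt, _qual(r_scores, loc, scale),
                            _depth(r_scores, lo, hi))
                )
            if in_truth:
                loc, scale = qd["truth"]
                truth_records.append(
                    _record(chrom, pos, ref, alt, _qual(r_scores, loc, scale),
                            _depth(r_scores, lo, hi))
                )

    # truth-side categories first (their own stream), then query-only ones
    plant("tp", zone_tc, c.tp, in_truth=True, in_query=True, pos_rng=r_truth)
    plant("i", zone_t_only, c.i, in_truth=True, in_query=False, pos_rng=r_truth)
    plant("fp", zone_tc, c.fp, in_truth=False, in_query=True, pos_rng=r_query)
    plant("nac", zone_t_only, c.nac, in_truth=False, in_query=True, pos_rng=r_query)
    plant("o", zone_c_only, c.o, in_truth=False, in_query=True, pos_rng=r_query)

    # decoys: sub-threshold query calls the filter stage must remove
    for chrom, pos in _sample_positions(zone_tc, spec.n_decoys, r_decoys, occupied):
        ref, alt = _draw_alleles(r_decoys, spec.ts_prob)
        if r_decoys.random() < 0.5:
            qual, depth = round(float(r_decoys.uniform(0.5, 15.0)), 2), _depth(r_decoys, lo, hi)
        else:
            qual, depth = _qual(r_decoys, *qd["fp"]), int(r_decoys.integers(0, 10))
        query_records.append(_record(chrom, pos, ref, alt, qual, depth))

    def _order(recs: List[VariantRecord]) -> Tuple[VariantRecord, ...]:
        return tuple(sorted(recs, key=lambda r: (r.chrom, r.pos)))

    return Fixture(
        spec=spec,
        truth_records=_order(truth_records),
        query_records=_order(query_records),
        target=target,
        confident=confident,
        expected=replace(c, fn=0),
        planted={k: tuple(v) for k, v in planted.items()},
    )


# ---------------------------------------------------------------------------
# multi-caller concordance fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrioFixture:
    """Query call sets for several callers with planted Venn cells."""

    names: Tuple[str, ...]
    queries: Mapping[str, Tuple[VariantRecord, ...]]
    expected_cells: Mapping[FrozenSet[str], int]
    target: RegionSet

    def key_sets(self) -> Dict[str, List[VariantKey]]:
        return {n: records_to_keys(list(recs)) for n, recs in self.queries.items()}

    def write(self, outdir) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, Path] = {}
        for name, recs in self.queries.items():
            paths[name] = outdir / f"{name}.vcf"
            write_vcf(list(recs), paths[name])
        paths["target"] = outdir / "target.bed"
        self.target.write_bed(paths["target"])
        manifest = {
            "cells": {"&".join(sorted(s)): n for s, n in self.expected_cells.items()},
        }
        paths["manifest"] = outdir / "manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return paths


def generate_trio(
    cells: Mapping[Iterable[str], int],
    chrom_length: int = 1_000_000,
    seed: int = 0,
    qual: Tuple[float, float] = (60.0, 10.0),
) -> TrioFixture:
    """Plant call sets whose Venn partition is exactly ``cells``.

    ``cells`` maps each caller subset (any iterable of names) to the
    exclusive count of variants shared by exactly those callers, e.g.
    ``{("a","b","c"): 251, ("b",): 52}``.  ``concordance()`` on the result
    returns precisely these cells (the test suite asserts this).
    """
    norm_cells: Dict[FrozenSet[str], int] = {}
    for subset, n in cells.items():
        key = frozenset([subset] if isinstance(subset, str) else subset)
        if not key:
            raise ValueError("empty caller subset in cells")
        if n < 0:
            raise ValueError("cell counts must be non-negative")
        if key in norm_cells:
            raise ValueError(f"duplicate cell {sorted(key)}")
        norm_cells[key] = int(n)
    names = tuple(sorted(frozenset().union(*norm_cells.keys())))
    if len(names) < 2:
        raise ValueError("need at least two callers")
    total = sum(norm_cells.values())
    if total > chrom_length:
        raise UnsatisfiableFixtureError(
            f"{total} variants requested on a {chrom_length} bp chromosome"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    positions = rng.choice(chrom_length, size=total, replace=False)
    queries: Dict[str, List[VariantRecord]] = {n: [] for n in names}
    idx = 0
    for subset in sorted(norm_cells, key=lambda s: sorted(s)):
        for _ in range(norm_cells[subset]):
            pos = int(positions[idx]) + 1
            idx += 1
            ref, alt = _draw_alleles(rng, 0.8)
            for name in subset:
                queries[name].append(
                    _record("1", pos, ref, alt, _qual(rng, *qual), _depth(rng, 20, 80))
                )
    target = RegionSet([("1", 0, chrom_length)])
    return TrioFixture(
        names=names,
        queries={
            n: tuple(sorted(v, key=lambda r: (r.chrom, r.pos))) for n, v in queries.items()
        },
        expected_cells=norm_cells,
        target=target,
    )
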