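"""VCF/BED input-output, quality filtering, and variant-key normalisation.

Variant identity throughout the package is :class:`VariantKey` —
``(chrom, pos, ref, alt)`` with the chromosome normalised (no ``chr``
prefix) and alleles upper-cased, exactly one alt per key.  Multiallelic
records are split into one key per alt; duplicate keys collapse when sets
are built.  No left-alignment or allele trimming is performed: the package
targets SNPs, for which the key is already canonical (a documented
limitation for indels, which are excluded by default anyway).

VCF reading and writing go through :mod:`pysam`; BED3+ is parsed here so
that malformed lines can be reported with exact line numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, NamedTuple, Optional, Sequence, Tuple

import pysam

from .errors import BedParseError, VcfParseError
from .intervals import RegionSet, normalize_chrom

__all__ = [
    "VariantRecord",
    "VariantKey",
    "GenotypedVariantKey",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "apply_quality_filters",
    "to_keys",
    "records_to_keys",
]

_BASES = frozenset("ACGTN")

# Effect annotations are stored as (gene, transcript, effect-class) triples,
# one per transcript, following the SnpEff/ANN convention of one entry per
# affected transcript.
Effect = Tuple[str, str, str]


class VariantKey(NamedTuple):
    """Normalized allele-level variant identity used for all set membership."""

    chrom: str
    pos: int
    ref: str
    alt: str


class GenotypedVariantKey(NamedTuple):
    """Variant identity extended with the unordered genotype allele multiset.

    Used by the optional genotype-aware matching mode: two calls match only
    if site, alleles, and called genotype all agree.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: Tuple[str, ...]


@dataclass(frozen=True)
class VariantRecord:
    """One parsed VCF data line.

    ``pos`` is 1-based.  ``depth`` is the DP value, preferring the sample
    FORMAT field over INFO.  ``effects`` holds transcript-level functional
    annotations as (gene, transcript, effect-class) triples; a single
    variant may carry several.
    """

    chrom: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    id: Optional[str] = None
    qual: Optional[float] = None
    filter_field: str = "."
    depth: Optional[int] = None
    genotype: Optional[Tuple[int, ...]] = None
    effects: Tuple[Effect, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF POS must be >= 1, got {self.pos}")
        if not self.ref or not self.alts:
            raise ValueError("REF and ALT must be non-empty")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def read_vcf(path, sample: Optional[str] = None) -> List[VariantRecord]:
    """Read a VCF 4.x file (plain or bgzipped) into VariantRecords, in file order.

    DP is taken from the named sample's FORMAT field when present, falling
    back to INFO/DP.  With multiple samples present, ``sample`` must name
    the one to read.  Malformed records raise :class:`VcfParseError` naming
    the 1-based data-record index.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError, FileNotFoundError) as exc:
        raise VcfParseError(f"{path}: cannot open/parse VCF header: {exc}") from exc
    records: List[VariantRecord] = []
    with vf:
        samples = list(vf.header.samples)
        if sample is None:
            if len(samples) > 1:
                raise VcfParseError(
                    f"{path}: {len(samples)} samples present; pass sample= to pick one"
                )
            sample = samples[0] if samples else None
        elif sample not in samples:
            raise VcfParseError(f"{path}: sample {sample!r} not in header {samples}")
        it = iter(vf)
        idx = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except Exception as exc:  # pysam raises bare errors on bad lines
                raise VcfParseError(
                    f"{path}: malformed VCF data record #{idx + 1}: {exc}"
                ) from exc
            idx += 1
            try:
                records.append(_convert_record(rec, sample))
            except Exception as exc:
                raise VcfParseError(
                    f"{path}: cannot interpret data record #{idx} "
                    f"({rec.chrom}:{rec.pos}): {exc}"
                ) from exc
    return records


def _info_get(rec: "pysam.VariantRecord", key: str):
    # pysam raises (rather than returning None) for keys absent from the header
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _convert_record(rec: "pysam.VariantRecord", sample: Optional[str]) -> VariantRecord:
    depth: Optional[int] = None
    genotype: Optional[Tuple[int, ...]] = None
    if sample is not None:
        fmt = rec.samples[sample]
        dp = fmt.get("DP")
        if dp is not None:
            depth = int(dp)
        gt = fmt.get("GT")
        if gt is not None and None not in gt:
            genotype = tuple(int(a) for a in gt)
    if depth is None:
        dp = _info_get(rec, "DP")
        if dp is not None:
            depth = int(dp[0] if isinstance(dp, tuple) else dp)

    effects: List[Effect] = []
    ann = _info_get(rec, "ANN")
    if ann:
        entries = ann if isinstance(ann, tuple) else (ann,)
        for entry in entries:
            parts = str(entry).split("|")
            effect = parts[1] if len(parts) > 1 else parts[0]
            gene = parts[3] if len(parts) > 3 else ""
            transcript = parts[6] if len(parts) > 6 else ""
            effects.append((gene, transcript, effect))

    filt = ";".join(rec.filter.keys()) or "."
    return VariantRecord(
        chrom=rec.chrom,
        pos=rec.pos,
        id=rec.id,
        ref=rec.ref.upper(),
        alts=tuple(a.upper() for a in (rec.alts or ())),
        qual=None if rec.qual is None else float(rec.qual),
        filter_field=filt,
        depth=depth,
        genotype=genotype,
        effects=tuple(effects),
    )


def read_bed(path) -> RegionSet:
    """Read a BED3+ file (0-based half-open) into a normalized RegionSet.

    Overlapping and adjacent intervals merge; chromosome names lose any
    ``chr`` prefix.  Bad coordinates raise :class:`BedParseError` with the
    file line number.
    """
    intervals: List[Tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise BedParseError(f"{path} line {lineno}: expected >=3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path} line {lineno}: invalid interval [{start},{end})"
                )
            intervals.append((cols[0], start, end))
    return RegionSet(intervals)


# ---------------------------------------------------------------------------
# filtering and key normalisation
# ---------------------------------------------------------------------------


def apply_quality_filters(
    records: Iterable[VariantRecord],
    min_qual: float = 20.0,
    min_depth: int = 10,
) -> List[VariantRecord]:
    """Keep records with ``QUAL > min_qual`` and ``DP > min_depth`` (strict).

    Records missing QUAL or DP are dropped (conservative, mirroring how
    hard filters on absent fields behave in common VCF filter tools).
    """
    if min_qual < 0 or min_depth < 0:
        raise ValueError("filter thresholds must be non-negative")
    return [
        r
        for r in records
        if r.qual is not None
        and r.depth is not None
        and r.qual > min_qual
        and r.depth > min_depth
    ]


def to_keys(
    record: VariantRecord,
    snp_only: bool = True,
    genotype_match: bool = False,
) -> List[VariantKey]:
    """Normalize one record into comparable keys, one per alt allele.

    Symbolic alleles and alts equal to the ref are dropped; with
    ``snp_only`` (the default — SNPs are this package's scope) any allele
    longer than one base is dropped too.  With ``genotype_match`` the keys
    carry the unordered set of called allele sequences, so matching demands
    genotype agreement.
    """
    chrom = normalize_chrom(record.chrom)
    ref = record.ref.upper()
    keys: List[VariantKey] = []
    for alt in record.alts:
        alt = alt.upper()
        if alt == ref or not alt or not set(alt) <= _BASES or not set(ref) <= _BASES:
            continue
        if snp_only and (len(ref) != 1 or len(alt) != 1):
            continue
        if genotype_match:
            alleles = (ref,) + record.alts
            if record.genotype is None:
                continue  # cannot genotype-match an uncalled record
            called = tuple(sorted(alleles[i].upper() for i in record.genotype))
            keys.append(GenotypedVariantKey(chrom, record.pos, ref, alt, called))
        else:
            keys.append(VariantKey(chrom, record.pos, ref, alt))
    return keys


def records_to_keys(
    records: Iterable[VariantRecord],
    snp_only: bool = True,
    genotype_match: bool = False,
) -> List[VariantKey]:
    """Keys for a whole call set: split, normalized, de-duplicated, file order."""
    seen = {}
    for rec in records:
        for key in to_keys(rec, snp_only=snp_only, genotype_match=genotype_match):
            seen.setdefault(key, None)
    return list(seen)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_vcf(records: Sequence[VariantRecord], path) -> None:
    """Write records as a valid VCF 4.2 file.

    Round-trip contract: ``read_vcf(write_vcf(X))`` preserves
    chrom/pos/ref/alt/qual (and DP, GT, ANN when present).  A sample column
    is emitted only if some record carries a genotype.
    """
    header = pysam.VariantHeader()
    contigs: List[str] = []
    filters: List[str] = []
    for rec in records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
        for name in rec.filter_field.split(";"):
            if name not in ("", ".", "PASS") and name not in filters:
                filters.append(name)
    for c in contigs:
        header.contigs.add(c)
    for f in filters:
        header.filters.add(f, None, None, "imported filter")
    header.add_meta(
        "INFO",
        items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
               ("Description", "Read depth")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "ANN"), ("Number", "."), ("Type", "String"),
               ("Description", "Functional annotations: Allele|Effect||Gene|||Transcript")],
    )
    with_sample = any(r.genotype is not None for r in records)
    if with_sample:
        header.add_meta(
            "FORMAT",
            items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                   ("Description", "Genotype")],
        )
        header.add_meta(
            "FORMAT",
            items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                   ("Description", "Read depth")],
        )
        header.add_sample("SAMPLE")

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref,) + rec.alts,
                id=rec.id,
                qual=rec.qual,
            )
            for name in rec.filter_field.split(";"):
                if name and name != ".":
                    vrec.filter.add(name)
            if rec.depth is not None:
                vrec.info["DP"] = rec.depth
            if rec.effects:
                vrec.info["ANN"] = tuple(
                    f"{rec.alts[0]}|{eff}||{gene}|||{tx}"
                    for gene, tx, eff in rec.effects
                )
            if with_sample:
                if rec.genotype is not None:
                    vrec.samples["SAMPLE"]["GT"] = rec.genotype
                if rec.depth is not None:
                    vrec.samples["SAMPLE"]["DP"] = rec.depth
            out.write(vrec)
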