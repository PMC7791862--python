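# Methods

## Variant identity and matching

All set membership uses the normalized key `(chrom, pos, ref, alt)`:
chromosome names lose any leading `chr` (case-insensitive), alleles are
upper-cased, multiallelic records are split into one key per alt, and
duplicate keys within a file collapse when sets are built.  No
left-alignment or trimming is applied: the package's scope is SNPs, whose
keys are already canonical; for indels (admitted via `snp_only=False`)
differently-represented equivalent alleles will not match, a documented
limitation.  A genotype-aware mode extends the key with the unordered
multiset of called allele sequences (`GenotypedVariantKey`), so a het/hom
disagreement at the same site no longer matches; it is off by default
because the category arithmetic is already reproducible at allele level.

Region membership of a variant uses its POS base only (`pos − 1` in
0-based half-open BED space).  That conversion is made exactly once, in
`intervals.RegionSet.contains`.

## Filtering

Query call sets pass a hard filter before benchmarking: QUAL > 20 and
DP > 10, both strict.  DP prefers the sample FORMAT field over INFO.
Records missing QUAL or DP are dropped — the conservative reading of a
hard filter over missing fields; the thresholds are arguments everywhere
they appear.  Truth sets are not filtered (a gold standard is curated
upstream).

## Category algebra

With `A = truth ∩ target`, `B = query ∩ target`, `C = query ∩ confident`:

TP = A∩B, FP = (B∩C)\A, FN = (A∩C)\B, NAC = B\(A∪C), O = C\(A∪B),
I = A\(B∪C).  True negatives are not computed: with no enumerable
universe of non-variant positions on a panel they have no stable meaning.
`DiscreteCounts.validate` asserts, on every construction, pairwise
disjointness, coverage of A∪B∪C, and the partition identities
`|B| = TP+FP+NAC` and `|A| = TP+FN+I`.

One structural fact deserves emphasis: **FN is identically empty** under
these definitions, for any input and any element-identity matching.  A
key in A has its position in the target; a key in C belongs to the query;
together that forces membership in B, so (A∩C)\B = ∅.  Missed truth
variants therefore surface in I (when outside the confident regions) or
not at all — which is also why the fixture generator rejects requests for
fn > 0 rather than silently emitting a bundle that cannot recover them.
Benchmarks that report non-zero FN (e.g. hap.py) define FN against
truth-in-confident directly rather than through C; this package
implements the set model faithfully instead.

## Interval algebra

`RegionSet` keeps, per chromosome, a sorted array of non-overlapping,
non-adjacent half-open intervals; adjacent intervals merge on
construction, so a covered-base set has exactly one representation and
structural equality is set equality.  Intersection and difference are
linear two-pointer sweeps; membership is a binary search.  The test suite
checks all of it against per-base bitmap oracles on ≤10 kb toy
chromosomes.

## Continuous metrics and summaries

Recall, precision, Frac_NA (= NAC/|B|) and F1 are computed unrounded; F1
is the harmonic mean of the *unrounded* precision and recall.  Zero
denominators raise `UndefinedMetricError`, rendered as `NA` in reports —
never 0 or 1.  Report rounding mirrors the conventional tables: 3
decimals for the four ratios, 5 for Ts/Tv, 4 for missense/silent.

Transitions are A↔G and C↔T; all other single-base substitutions are
transversions; non-SNP keys are unclassifiable and excluded from both
tallies.  Functional-class counting is transcript-level: every
(gene, transcript, effect) annotation entry counts once, so totals may
exceed the variant count; labels map case-insensitively
(`missense_variant`/`missense` → missense,
`synonymous_variant`/`synonymous`/`silent` → silent) and anything else is
ignored by the ratio.  The variant-rate denominator is
`round(span / n)` with the reference span configurable, defaulting to the
GRCh37 primary-chromosome total (3 095 677 412 bp); no single span is
consistent with all published panel rates, so the choice is explicit
rather than implied.

## ROC analysis

Scored calls are the elements of B; the default label is membership in A
(concordant vs not) and the default score is QUAL — both are explicit
arguments, and the CLI records the definitions in its JSON output.  The
curve comes from grouping tied scores at single thresholds
(scikit-learn's sweep with no intermediate-point dropping); the AUC is
computed by mid-rank Mann–Whitney statistics and equals the trapezoidal
area under the emitted points to 1e−12 (asserted in tests).

The single-curve standard error is Hanley–McNeil's closed form, which at
AUC = 0.5 coincides with the exact Mann–Whitney null standard deviation
√((m+n+1)/(12mn)) — the property the null-calibration test exploits: with
50 calls per class and label-independent scores, the two-sided z-test
p-values are uniform (Kolmogorov–Smirnov check over 2 000 replicates).
Unpaired curve comparison pools the two SEs; the paired mode uses
DeLong's covariance of placement values over the calls the two pipelines
share, erroring when they share none.  p-values below 5e−4 print as
`0.000` in reports, with exact values kept in JSON.

## Synthetic fixtures

The generator emulates a small capture panel.  Defaults: two 200 kb
chromosomes; target and confident regions drawn as independent 1 kb
blocks covering ≈30% and ≈55% of each chromosome, so all overlap zones
(target∩confident, target-only, confident-only) occur with room to
spare; alleles drawn with transition probability 0.8 (expected Ts/Tv ≈ 4,
typical of coding panels); DP uniform on 20–80; QUAL normal per category,
concordant calls scoring higher than discordant ones (so ROC fixtures
separate), clipped above the filter threshold so every planted call
survives filtering.  Optional decoys are sub-threshold calls (low QUAL or
low DP) that the filter stage must remove; tests assert they never reach
any category.

Each requested category is planted in the zone whose membership signature
produces it, positions drawn without collision; the central contract —
`compute_discrete(build_sets(generate(spec)))` recovers `spec.counts`
exactly — is exercised over hundreds of random specs.  Randomness uses
independent child streams (regions, truth, query, scores, decoys) spawned
from one seed, so enabling decoys does not perturb the other draws and
identical spec+seed yields byte-identical files.

`generate_trio` plants multi-caller concordance directly from requested
Venn cells (a mapping from caller subsets to exclusive counts), which is
the exact quantity `concordance()` must recover; it was specified more
loosely as shared-truth fixtures plus an overlap matrix, but the cell
mapping is the same information with a sharper contract.

What the generator does **not** emulate: read-level error, mapping
artefacts, clustered indels, allele-frequency structure, or
representation ambiguity.  Passing tests therefore demonstrate the
correctness of the set algebra, filtering, I/O and statistics — not that
any particular caller is well-behaved on real reads.

## Problem sizes

The test suite runs synthetic instances of a few hundred to a thousand
variants and regions of tens to hundreds of kilobases — ample for exact
combinatorial checks, and the full suite completes in a few seconds.  The
acceptance script uses the same scales (100-replicate recovery sweeps,
2 000-replicate calibration in tests).

## Known limitations

* Allele-level matching cannot distinguish genotype errors unless the
  genotype-aware mode is enabled, and neither mode performs haplotype
  (vcfeval-style) comparison.
* Indel re-representation is not normalized.
* FN ≡ ∅ structurally (see above); users wanting hap.py-style FN should
  read I together with FN.
* Venn tables are emitted as TSV only; no Venn figure is drawn.
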