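# vcbench

Set-theory benchmarking of variant-calling pipelines for targeted
sequencing.

Clinical gene panels (cardiomyopathy, arrhythmia and similar inherited
cardiac condition panels among them) depend on variant callers whose
outputs disagree, so pipelines must be validated against a gold-standard
sample — typically NA12878, with a curated truth VCF and high-confidence
BED regions.  Generic comparison engines do this matching opaquely.
`vcbench` implements the transparent alternative: plain set algebra over
normalized variant identities, so every metric decomposes into an
inspectable variant list.

## The model

From a truth call set, a query call set, the capture-target regions and
the high-confidence regions, three sets of variant keys
`(chrom, pos, ref, alt)` are built:

```
A = truth ∩ target      B = query ∩ target      C = query ∩ confident
```

Six pairwise-disjoint categories follow by set operations:

```
TP  = A ∩ B         FP  = (B ∩ C) \ A     FN  = (A ∩ C) \ B
NAC = B \ (A ∪ C)   O   = C \ (A ∪ B)     I   = A \ (B ∪ C)
```

— true positives, false positives, false negatives, non-assessed calls,
out-of-target confident-region calls, and incongruences (truth variants
outside the confident regions that the caller missed).  True negatives
are deliberately not computed.  Continuous metrics are the usual ratios:

```
Recall    = TP / (TP + FN)          Precision = TP / (TP + FP)
Frac_NA   = NAC / |B|               F1        = 2·P·R / (P + R)
```

On top of this sit call-set summaries (Ts/Tv ratio, transcript-level
missense/silent ratio, per-chromosome counts, variant rate), n-caller
Venn concordance, and ROC/AUC comparison of callers (rank AUC with
Hanley–McNeil standard errors, normal z-tests, and DeLong's paired test).
A seeded generator fabricates complete benchmark bundles — truth VCF,
query VCF, target BED, confident BED — with *exactly* requested category
counts, so the whole pipeline is testable without external downloads.

Before filtering, query VCFs pass the panel-standard hard filter
QUAL > 20 and DP > 10 (strict inequalities; records missing either field
are dropped).

## Worked example

```python
from vcbench import (CategoryCounts, FixtureSpec, generate, records_to_keys,
                     apply_quality_filters, build_sets, compute_discrete,
                     continuous_metrics)

fx = generate(FixtureSpec(counts=CategoryCounts(tp=233, fp=3, nac=23, i=2),
                          n_decoys=10, seed=42))
truth = records_to_keys(fx.truth_records)
query = records_to_keys(apply_quality_filters(fx.query_records))
counts = compute_discrete(build_sets(truth, query, fx.target, fx.confident))
print(counts.as_dict())
print(continuous_metrics(counts))
```

prints

```
{'tp': 233, 'fp': 3, 'fn': 0, 'nac': 23, 'o': 0, 'i': 2}
ContinuousMetrics(recall=1.0, precision=0.9872881355932204, frac_na=0.08880308880308881, f1=0.9936034115138592)
```

The ten sub-threshold decoy calls were removed by the quality filter; the
233 + 3 + 23 = 259 surviving assessed calls partition exactly into
TP/FP/NAC; recall 1.000 means every assessable truth variant was found,
and precision 0.987 reflects the 3 false positives among 236 assessable
calls.  More scripts live in `examples/` (one per capability:
benchmarking, concordance, ROC comparison, region overlap).

The same pipeline is available from the shell:

```sh
vcbench simulate --tp 233 --fp 3 --nac 23 --i-count 2 --decoys 10 --outdir fix
vcbench bench --truth fix/truth.vcf --query caller=fix/query.vcf \
              --target fix/target.bed --confident fix/confident.bed --outdir out
vcbench roc   --truth fix/truth.vcf --query caller=fix/query.vcf \
              --target fix/target.bed --confident fix/confident.bed --outdir roc
```

`bench` writes a metrics table (TSV + JSON), one VCF per category, the
region-overlap summary and, for several queries, the Venn cell table.

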