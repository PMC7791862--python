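"""Interval algebra: how much of a capture target is high-confidence?

Builds a toy capture manifest and a high-confidence region set, intersects
them and reports the covered fraction — the same computation `vcbench
bench` logs for real BED pairs.
"""

from vcbench import RegionSet, intersect, total_length

target = RegionSet(
    [("1", 1_000, 6_000), ("1", 10_000, 14_000), ("7", 0, 3_000)]
)
confident = RegionSet(
    [("chr1", 2_000, 12_000), ("chr7", 1_500, 2_500)]  # "chr" dialect merges fine
)

overlap = intersect(target, confident)
pct = 100.0 * total_length(overlap) / total_length(target)

print(f"target length    : {total_length(target):>6d} bp")
print(f"confident length : {total_length(confident):>6d} bp")
print(f"intersection     : {total_length(overlap):>6d} bp")
print(f"-> {pct:.1f}% of the target is high-confidence")
for region in overlap:
    print(f"   {region.chrom}:{region.start}-{region.end}")
# Only calls inside the intersection can be scored as TP/FP/FN; the rest of
# the target yields NAC (non-assessed) calls.
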