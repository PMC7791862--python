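"""Three-caller concordance: plant known Venn cells and recover them.

Builds three query call sets sharing a planted overlap structure (251
variants common to all three, 52 exclusive to one caller, small pairwise
fringes) and tabulates every cell of the Venn partition.
"""

from vcbench import concordance, generate_trio

trio = generate_trio(
    {
        ("freebayes", "varscan", "isaac"): 251,
        ("varscan",): 52,
        ("freebayes", "varscan"): 6,
        ("freebayes",): 1,
        ("freebayes", "isaac"): 1,
        ("isaac",): 1,
        ("varscan", "isaac"): 2,
    },
    seed=6,
)

key_sets = trio.key_sets()
for name, keys in sorted(key_sets.items()):
    print(f"{name}: {len(keys)} SNPs")

table = concordance(key_sets)
print(f"\ncommon to all three : {table.common}")
print(f"varscan exclusive   : {table.cell('varscan')}")
print("\nall Venn cells (exclusive counts, summing to the union):")
for label, count in table.rows():
    print(f"  {label:30s} {count}")
# The per-caller totals (259/311/255) are the row sums of these cells; the
# centre cell is the variants every pipeline agrees on.
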