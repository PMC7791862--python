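"""Set construction, the six-category algebra, and multi-caller concordance."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from vcbench.benchmark import (
    BenchmarkSets,
    build_sets,
    compute_discrete,
    concordance,
)
from vcbench.errors import VcbenchError
from vcbench.intervals import RegionSet
from vcbench.vcfio import VariantKey


def K(pos, chrom="1"):
    return VariantKey(chrom, pos, "A", "G")


def sets_from(a, b, c):
    return BenchmarkSets(a=frozenset(a), b=frozenset(b), c=frozenset(c))


def brute_force_categories(a, b, c):
    """Independent oracle: classify each key by its (∈A, ∈B, ∈C) signature."""
    table = {
        (True, True, True): "tp",
        (True, True, False): "tp",
        (False, True, True): "fp",
        (True, False, True): "fn",
        (False, True, False): "nac",
        (False, False, True): "o",
        (True, False, False): "i",
    }
    out = {name: set() for name in ("tp", "fp", "fn", "nac", "o", "i")}
    for key in set(a) | set(b) | set(c):
        out[table[(key in a, key in b, key in c)]].add(key)
    return out


small_key_sets = st.sets(st.integers(1, 40).map(K), max_size=25)


class TestBuildSets:
    def test_definitions_on_full_coverage(self):
        k1, k2, k3 = K(10), K(20), K(30)
        everywhere = RegionSet([("1", 0, 100)])
        s = build_sets([k1, k2], [k1, k3], everywhere, everywhere)
        assert s.a == {k1, k2} and s.b == {k1, k3} and s.c == {k1, k3}

    def test_empty_confident_gives_empty_c(self):
        target = RegionSet([("1", 0, 100)])
        s = build_sets([K(10)], [K(10), K(20)], target, RegionSet())
        assert s.c == frozenset() and s.b == {K(10), K(20)}

    def test_empty_target_is_an_error(self):
        with pytest.raises(VcbenchError, match="target"):
            build_sets([K(10)], [K(10)], RegionSet(), RegionSet([("1", 0, 5)]))

    def test_random_keys_match_brute_force_double_filter(self, rng):
        keys = [K(int(p) + 1) for p in rng.choice(5000, size=500, replace=False)]
        truth, query = keys[:300], keys[200:]
        starts = rng.integers(0, 4900, size=40)
        target = RegionSet(("1", int(s), int(s + rng.integers(1, 200))) for s in starts)
        starts = rng.integers(0, 4900, size=40)
        confident = RegionSet(("1", int(s), int(s + rng.integers(1, 200))) for s in starts)
        s = build_sets(truth, query, target, confident)
        assert s.a == {k for k in truth if target.contains(k.chrom, k.pos)}
        assert s.b == {k for k in query if target.contains(k.chrom, k.pos)}
        assert s.c == {k for k in query if confident.contains(k.chrom, k.pos)}


class TestComputeDiscrete:
    def test_hand_enumerated_example(self):
        a, b, c, d, e = (K(i) for i in range(1, 6))
        counts = compute_discrete(sets_from({a, b}, {a, c, d}, {a, c, e}))
        assert counts.tp_keys == {a}
        assert counts.fp_keys == {c}
        assert counts.fn_keys == set()
        assert counts.nac_keys == {d}
        assert counts.o_keys == {e}
        assert counts.i_keys == {b}

    def test_identical_sets_all_tp(self):
        ks = {K(1), K(2), K(3)}
        counts = compute_discrete(sets_from(ks, ks, ks))
        assert counts.tp_keys == ks
        assert counts.fp == counts.fn == counts.nac == counts.o == counts.i == 0

    def test_empty_truth_degenerate(self):
        b = {K(1), K(2)}
        c = {K(2), K(3)}
        counts = compute_discrete(sets_from(set(), b, c))
        assert counts.tp == counts.fn == counts.i == 0
        assert counts.fp_keys == b & c
        assert counts.nac_keys == b - c
        assert counts.o_keys == c - b

    @given(small_key_sets, small_key_sets, small_key_sets)
    def test_matches_signature_oracle_and_partitions(self, a, b, c):
        counts = compute_discrete(sets_from(a, b, c))
        oracle = brute_force_categories(a, b, c)
        for name, keys in oracle.items():
            assert getattr(counts, f"{name}_keys") == keys, name
        # partition identities
        assert counts.tp + counts.fp + counts.nac == len(b)
        assert counts.tp + counts.fn + counts.i == len(a)
        assert len(c) == len(a & c) + counts.fp + counts.o

    @given(small_key_sets, small_key_sets, small_key_sets)
    def test_fn_structurally_empty(self, a, b, c):
        # membership in A and C implies membership in B is not required for
        # arbitrary abstract sets, but FN keys must lie in both A and C and
        # outside B by definition — compute_discrete realises exactly that.
        counts = compute_discrete(sets_from(a, b, c))
        assert counts.fn_keys == (a & c) - b

    def test_input_order_is_irrelevant(self, rng):
        keys = [K(int(p) + 1) for p in rng.choice(1000, size=60, replace=False)]
        region = RegionSet([("1", 0, 1001)])
        s1 = build_sets(keys[:40], keys[20:], region, region)
        perm = list(keys)
        rng.shuffle(perm)
        s2 = build_sets(
            [k for k in perm if k in keys[:40]],
            [k for k in perm if k in keys[20:]],
            region,
            region,
        )
        assert compute_discrete(s1).as_dict() == compute_discrete(s2).as_dict()

    def test_category_lists_deterministically_ordered(self):
        ks = {K(5), K(2, chrom="2"), K(9), VariantKey("1", 5, "A", "C")}
        counts = compute_discrete(sets_from(ks, ks, ks))
        assert counts.keys_of("tp") == [
            VariantKey("1", 5, "A", "C"),
            K(5),
            K(9),
            K(2, chrom="2"),
        ]


class TestConcordance:
    def test_two_sets(self):
        x, y, z = K(1), K(2), K(3)
        table = concordance({"p": {x, y}, "q": {y, z}})
        assert table.cell("p", "q") == 1
        assert table.cell("p") == 1 and table.cell("q") == 1
        assert table.pairwise[("p", "q")] == 1

    def test_three_identical_sets_center_only(self):
        ks = {K(i) for i in range(5)}
        table = concordance({"a": ks, "b": ks, "c": ks})
        assert table.common == 5
        assert table.total() == 5
        assert table.cell("a") == table.cell("a", "b") == 0

    def test_requires_two_sets(self):
        with pytest.raises(VcbenchError):
            concordance({"only": {K(1)}})

    def test_random_trio_matches_signature_tally(self, rng):
        pool = [K(int(p) + 1) for p in rng.choice(500, size=150, replace=False)]
        sets = {
            name: {k for k in pool if rng.random() < 0.5}
            for name in ("a", "b", "c")
        }
        table = concordance(sets)
        union = set().union(*sets.values())
        assert table.total() == len(union)
        tally = {}
        for key in union:
            sig = frozenset(n for n, s in sets.items() if key in s)
            tally[sig] = tally.get(sig, 0) + 1
        assert dict(table.cells) == tally
        for (x, y), n in table.pairwise.items():
            assert n == len(sets[x] & sets[y])
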