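"""CNVR algebra against brute-force oracles and closed-form fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import mk_call, random_calls
from rdcnv import (Cnvr, differential_cnvrs, find_common_cnvs,
                   group_common_cnvrs, merge_cnvs, reciprocal_overlap,
                   split_shared_specific)
from rdcnv.genome import Interval, overlap_bp


def brute_force_common(calls_by_individual, threshold=0.3, same_type=True):
    """O(n^2) all-pairs oracle for common-CNV detection."""
    flat = [(ind, c) for ind, cs in calls_by_individual.items() for c in cs]
    out = set()
    for i, (ia, a) in enumerate(flat):
        for ib, b in flat:
            if ia == ib:
                continue
            if same_type and a.type != b.type:
                continue
            fa, fb = reciprocal_overlap(a, b)
            if fa > threshold and fb > threshold:
                out.add(a)
                out.add(b)
    return out


class TestReciprocalOverlap:
    @pytest.mark.parametrize("a,b,expect", [
        ((0, 100), (0, 100), (1.0, 1.0)),
        ((0, 100), (50, 150), (0.5, 0.5)),
        ((0, 100), (200, 300), (0.0, 0.0)),
        ((0, 1000), (900, 1100), (0.1, 0.5)),
    ])
    def test_known_fractions(self, a, b, expect):
        ia, ib = Interval("chr1", *a), Interval("chr1", *b)
        assert reciprocal_overlap(ia, ib) == pytest.approx(expect)

    def test_different_chromosomes_are_disjoint(self):
        a, b = Interval("chr1", 0, 100), Interval("chr2", 0, 100)
        assert reciprocal_overlap(a, b) == (0.0, 0.0)

    def test_zero_length_interval_rejected(self):
        class Stub:
            chrom, start, end = "chr1", 5, 5
        with pytest.raises(ValueError):
            reciprocal_overlap(Stub(), Interval("chr1", 0, 10))

    @settings(max_examples=100, derandomize=True)
    @given(s1=st.integers(0, 1000), l1=st.integers(1, 500),
           s2=st.integers(0, 1000), l2=st.integers(1, 500))
    def test_symmetry_and_bounds(self, s1, l1, s2, l2):
        a = Interval("chr1", s1, s1 + l1)
        b = Interval("chr1", s2, s2 + l2)
        fa, fb = reciprocal_overlap(a, b)
        fb2, fa2 = reciprocal_overlap(b, a)
        assert (fa, fb) == (fa2, fb2)
        assert 0 <= fa <= 1 and 0 <= fb <= 1


class TestFindCommon:
    def test_single_individual_yields_nothing(self):
        calls = {"s1": [mk_call(start=0, end=10_000)]}
        assert find_common_cnvs(calls) == set()

    def test_identical_calls_across_individuals_both_common(self):
        a = mk_call(sample="s1")
        b = mk_call(sample="s2")
        assert find_common_cnvs({"s1": [a], "s2": [b]}) == {a, b}

    def test_threshold_is_strict(self):
        # exactly 30% reciprocal overlap must NOT qualify
        a = mk_call(sample="s1", start=0, end=1_000)
        b = mk_call(sample="s2", start=700, end=1_700)
        assert reciprocal_overlap(a, b) == (0.3, 0.3)
        assert find_common_cnvs({"s1": [a], "s2": [b]}, threshold=0.3) == set()

    def test_type_matching_required_by_default(self):
        a = mk_call(sample="s1", type="deletion")
        b = mk_call(sample="s2", type="duplication", rd=1.6, cn=3)
        assert find_common_cnvs({"s1": [a], "s2": [b]}) == set()
        assert find_common_cnvs({"s1": [a], "s2": [b]},
                                require_same_type=False) == {a, b}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        samples = ["s1", "s2", "s3", "s4"]
        calls = random_calls(rng, 40, samples, chroms=("chr1", "chr2"))
        by_ind = {s: [c for c in calls if c.sample_id == s] for s in samples}
        assert find_common_cnvs(by_ind) == brute_force_common(by_ind)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), threshold=st.sampled_from([0.1, 0.3, 0.5]))
    def test_oracle_equivalence_property(self, seed, threshold):
        rng = np.random.default_rng(seed)
        samples = ["a", "b", "c"]
        calls = random_calls(rng, 25, samples, max_pos=30_000)
        by_ind = {s: [c for c in calls if c.sample_id == s] for s in samples}
        assert find_common_cnvs(by_ind, threshold) == \
            brute_force_common(by_ind, threshold)


class TestMerge:
    def test_abutting_halfopen_intervals_not_merged(self):
        a = mk_call(start=0, end=100_00)
        b = mk_call(start=100_00, end=200_00, sample="s2")
        assert len(merge_cnvs([a, b])) == 2

    def test_one_bp_overlap_merges(self):
        a = mk_call(start=0, end=10_000)
        b = mk_call(start=9_999, end=20_000, sample="s2")
        merged = merge_cnvs([a, b])
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 20_000)
        assert merged[0].samples == frozenset({"high1", "s2"})

    def test_empty_input_empty_output(self):
        assert merge_cnvs([]) == []

    def test_chain_merging_is_transitive(self):
        a = mk_call(start=0, end=10_000)
        b = mk_call(start=9_000, end=19_000)
        c = mk_call(start=18_000, end=28_000)
        merged = merge_cnvs([a, b, c])
        assert len(merged) == 1 and merged[0].end - merged[0].start == 28_000

    def test_mixed_types_categorised_both(self):
        a = mk_call(start=0, end=10_000, type="deletion")
        b = mk_call(start=5_000, end=15_000, type="duplication", rd=1.6, cn=3)
        assert merge_cnvs([a, b])[0].category == "both"

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(0, 30))
    def test_idempotence_and_base_conservation(self, seed, n):
        rng = np.random.default_rng(seed)
        calls = random_calls(rng, n, ["s1", "s2"], max_pos=50_000)
        merged = merge_cnvs(calls)
        assert merge_cnvs(merged) == [
            Cnvr(c.chrom, c.start, c.end, c.category, c.samples, c.groups,
                 c.source_calls) for c in merged]
        # every input base is covered by exactly one merged region
        for call in calls:
            covering = [m for m in merged
                        if m.chrom == call.chrom
                        and m.start <= call.start and call.end <= m.end]
            assert len(covering) == 1
        # merged regions never overlap each other
        for i, a in enumerate(merged):
            for b in merged[i + 1:]:
                assert overlap_bp(a, b) == 0


class TestGroupCommon:
    def test_no_commonality_yields_empty(self):
        calls = {"s1": [mk_call(start=0, end=10_000)],
                 "s2": [mk_call(start=50_000, end=60_000)]}
        assert group_common_cnvrs(calls, group_name="high") == []

    def test_jittered_event_shared_by_four_gives_one_cnvr(self):
        base = 100_000
        calls = {
            f"s{i}": [mk_call(sample=f"s{i}", start=base + i * 500,
                              end=base + 20_000 + i * 300)]
            for i in range(4)
        }
        cnvrs = group_common_cnvrs(calls, group_name="high")
        assert len(cnvrs) == 1
        assert cnvrs[0].samples == frozenset(calls)
        assert cnvrs[0].groups == frozenset({"high"})


class TestSplitSharedSpecific:
    def make(self, start, end, category="deletion", group="high"):
        return Cnvr("chr1", start, end, category, frozenset({"x"}),
                    frozenset({group}))

    def test_identical_sets_all_shared(self):
        high = [self.make(0, 10_000)]
        low = [self.make(0, 10_000, group="low")]
        shared, hi, lo = split_shared_specific(high, low)
        assert len(shared) == 2 and hi == [] and lo == []

    def test_disjoint_sets_all_specific(self):
        high = [self.make(0, 10_000)]
        low = [self.make(50_000, 60_000, group="low")]
        shared, hi, lo = split_shared_specific(high, low)
        assert shared == [] and hi == high and lo == low

    def test_outputs_partition_inputs_on_mixed_fixture(self):
        high = [self.make(i * 50_000, i * 50_000 + 8_000) for i in range(10)]
        # 4 low CNVRs paired to the first 4 high ones at RO > 0.3
        low = [self.make(c.start + 2_000, c.end + 2_000, group="low")
               for c in high[:4]]
        low += [self.make(600_000 + i * 20_000, 608_000 + i * 20_000, group="low")
                for i in range(6)]
        shared, hi, lo = split_shared_specific(high, low)
        # brute-force check of the criterion
        def is_shared(c, others):
            return any(min(reciprocal_overlap(c, o)) > 0.3 for o in others)
        assert sorted(x.start for x in shared) == sorted(
            [c.start for c in high if is_shared(c, low)] +
            [c.start for c in low if is_shared(c, high)])
        assert len(shared) == 8 and len(hi) == 6 and len(lo) == 6
        assert len(shared) + len(hi) + len(lo) == len(high) + len(low)

    def test_overlap_criterion_variant(self):
        high = [self.make(0, 100_000)]
        low = [self.make(99_999, 200_000, group="low")]  # 1 bp, RO tiny
        shared_ro, _, _ = split_shared_specific(high, low, "reciprocal")
        shared_bp, _, _ = split_shared_specific(high, low, "overlap")
        assert shared_ro == [] and len(shared_bp) == 2


class TestDifferential:
    def test_disjoint_specifics_concatenate(self):
        hi = [Cnvr("chr1", 0, 10_000, "deletion", frozenset({"a"}), frozenset({"high"}))]
        lo = [Cnvr("chr1", 50_000, 60_000, "duplication", frozenset({"b"}), frozenset({"low"}))]
        diff = differential_cnvrs(hi, lo)
        assert len(diff) == len(hi) + len(lo)

    def test_cross_group_overlap_merges_to_both(self):
        hi = [Cnvr("chr1", 0, 10_000, "duplication", frozenset({"a"}), frozenset({"high"}))]
        lo = [Cnvr("chr1", 9_999, 20_000, "deletion", frozenset({"b"}), frozenset({"low"}))]
        diff = differential_cnvrs(hi, lo)
        assert len(diff) == 1
        assert diff[0].category == "both"
        assert diff[0].groups == frozenset({"high", "low"})

    def test_empty_inputs(self):
        assert differential_cnvrs([], []) == []

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 5_000))
    def test_count_never_exceeds_sum_of_specifics(self, seed):
        rng = np.random.default_rng(seed)
        mk = lambda s, grp: Cnvr("chr1", s, s + 5_000, "deletion",
                                 frozenset({"x"}), frozenset({grp}))
        hi = [mk(int(s), "high") for s in rng.integers(0, 100_000, 8)]
        hi = merge_cnvs(hi)
        lo = [mk(int(s), "low") for s in rng.integers(0, 100_000, 8)]
        lo = merge_cnvs(lo)
        assert len(differential_cnvrs(hi, lo)) <= len(hi) + len(lo)
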