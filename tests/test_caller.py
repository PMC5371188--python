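"""Caller stages: GC correction, segmentation, calling, QC filtering."""

import numpy as np
import pytest

from conftest import mk_call
from rdcnv import (Chromosome, GenomeSpec, Interval, TruthSet, build_truth,
                   call_sample, make_genome, recovery_metrics, simulate_bins,
                   simulate_cohort)
from rdcnv.caller import (RdProfile, call_cnvs, gc_correct, qc_filter, segment)
from rdcnv.simulate import BinTrack, ChromBins


def make_track(counts, gc=None, q0=None, sample="s1", bin_size=200):
    counts = np.asarray(counts)
    n = len(counts)
    track = BinTrack(sample_id=sample, bin_size=bin_size)
    track.chroms["chr1"] = ChromBins(
        counts=counts.astype(np.int64),
        gc=np.full(n, 0.45) if gc is None else np.asarray(gc),
        q0=np.full(n, 0.05) if q0 is None else np.asarray(q0),
    )
    return track


def profile_from(rd, q0=None, sample="s1", bin_size=200) -> RdProfile:
    rd = np.asarray(rd, dtype=float)
    return RdProfile(
        sample_id=sample, bin_size=bin_size,
        rd={"chr1": rd},
        q0={"chr1": np.full(len(rd), 0.05) if q0 is None else np.asarray(q0)},
        baseline_cn_by_chrom={"chr1": 2},
    )


class TestGcCorrect:
    def test_constant_counts_normalise_to_one(self):
        prof = gc_correct(make_track([20] * 2_000))
        assert np.allclose(prof.rd["chr1"], 1.0)

    def test_unbiased_track_close_to_plain_normalisation(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(20.0, 20_000)
        gc = 0.45 + 0.1 * np.sin(np.arange(20_000) / 500)
        prof = gc_correct(make_track(counts, gc=gc))
        plain = counts / counts[counts > 0].mean()
        # correction factors are estimated, so allow small wiggle
        assert np.allclose(prof.rd["chr1"], plain, rtol=0.03, atol=0.02)

    def test_simulated_bias_is_removed(self):
        # after correction the median RD in every GC decile sits near 1
        genome = GenomeSpec([Chromosome("chr1", 10_000_000)], bin_size=200)
        truth = TruthSet(genome=genome, samples=[("s1", "high")], events=[], seed=0)
        track = simulate_bins(truth, "s1", 20.0, gc_bias_amplitude=0.3, seed=5)
        prof = gc_correct(track)
        gc = track.chroms["chr1"].gc
        rd = prof.rd["chr1"]
        edges = np.quantile(gc, np.linspace(0.1, 0.9, 9))
        for d in range(10):
            sel = np.searchsorted(edges, gc, side="right") == d
            assert abs(np.median(rd[sel]) - 1.0) < 0.05

    def test_autosomal_mean_is_one(self):
        rng = np.random.default_rng(1)
        prof = gc_correct(make_track(rng.poisson(20, 5_000)))
        rd = prof.rd["chr1"]
        assert abs(rd[rd > 0].mean() - 1.0) < 0.01

    def test_haploid_chromosome_rescaled_to_diploid_scale(self):
        rng = np.random.default_rng(2)
        track = make_track(rng.poisson(20, 5_000))
        track.chroms["chrX"] = ChromBins(
            counts=rng.poisson(10, 5_000).astype(np.int64),
            gc=np.full(5_000, 0.45), q0=np.full(5_000, 0.05))
        prof = gc_correct(track, {"chr1": 2, "chrX": 1})
        assert abs(prof.rd["chrX"].mean() - 1.0) < 0.05

    def test_all_zero_track_is_an_error(self):
        with pytest.raises(ValueError, match="no coverage"):
            gc_correct(make_track([0] * 1_000))


class TestSegment:
    def test_flat_profile_yields_nothing(self):
        assert segment(profile_from([1.0] * 100)) == []

    def test_single_low_block_is_one_segment(self):
        rd = [1.0] * 30 + [0.4] * 30 + [1.0] * 30
        segs = segment(profile_from(rd), smooth_window=1)
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.start_bin, seg.end_bin, seg.side) == (30, 60, "low")

    def test_bridging_merges_across_single_neutral_bin(self):
        rd = [0.4] * 10 + [1.0] + [0.4] * 10
        bridged = segment(profile_from(rd), max_bridge=1, smooth_window=1)
        strict = segment(profile_from(rd), max_bridge=0, smooth_window=1)
        assert [(s.start_bin, s.end_bin) for s in bridged] == [(0, 21)]
        assert [(s.start_bin, s.end_bin) for s in strict] == [(0, 10), (11, 21)]

    def test_opposite_side_bin_never_bridged(self):
        rd = [0.4] * 10 + [1.6] + [0.4] * 10
        segs = segment(profile_from(rd), max_bridge=2, smooth_window=1,
                       dup_confirm=None)
        lows = [(s.start_bin, s.end_bin) for s in segs if s.side == "low"]
        assert lows == [(0, 10), (11, 21)]

    def test_confirmation_drops_marginal_runs(self):
        rd = [1.0] * 30 + [1.29] * 30 + [1.0] * 30  # past enter, below confirm
        assert segment(profile_from(rd), smooth_window=1) == []
        kept = segment(profile_from(rd), smooth_window=1, dup_confirm=None)
        assert len(kept) == 1

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            segment(profile_from([1.0]), del_enter=1.2)


class TestCallCnvs:
    def test_homozygous_deletion_call(self):
        rd = np.array([1.0] * 20 + [0.0] * 20 + [1.0] * 20)
        prof = profile_from(rd)
        calls = call_cnvs(prof, segment(prof, smooth_window=1))
        assert len(calls) == 1
        c = calls[0]
        assert (c.type, c.estimated_cn) == ("deletion", 0)
        assert (c.start, c.end) == (20 * 200, 40 * 200)
        assert c.p_value == 0.0  # zero variance away from 1

    def test_doubled_depth_gives_cn4_duplication(self):
        rng = np.random.default_rng(3)
        rd = np.concatenate([np.ones(20), 2.0 + rng.normal(0, 0.01, 20), np.ones(20)])
        prof = profile_from(rd)
        calls = call_cnvs(prof, segment(prof, smooth_window=1))
        assert len(calls) == 1
        assert calls[0].type == "duplication"
        assert calls[0].estimated_cn == 4
        assert calls[0].p_value < 1e-6

    def test_single_bin_segment_gets_p_one(self):
        from rdcnv.caller import Segment
        prof = profile_from([1.0, 0.4, 1.0])
        calls = call_cnvs(prof, [Segment("chr1", 1, 2, "low")])
        assert calls[0].p_value == 1.0

    def test_call_q0_is_mean_of_bin_q0(self):
        q0 = np.array([0.1] * 10 + [0.7] * 10 + [0.1] * 10)
        rd = np.array([1.0] * 10 + [0.4] * 10 + [1.0] * 10)
        prof = profile_from(rd, q0=q0)
        calls = call_cnvs(prof, segment(prof, smooth_window=1))
        assert calls[0].q0 == pytest.approx(0.7)


class TestQcFilter:
    def test_individual_criteria(self):
        gaps = [Interval("chr1", 50_000, 60_000)]
        keep = mk_call(start=0, end=2_000, p=1e-5)
        assert qc_filter([keep], gaps) == [keep]
        assert qc_filter([mk_call(p=0.02)], gaps) == []            # p >= 0.01
        assert qc_filter([mk_call(start=0, end=1_000)], gaps) == []  # size not > 1 kb
        assert qc_filter([mk_call(q0=0.6)], gaps) == []            # q0 >= 0.5
        assert qc_filter([mk_call(chrom="chrUn")], gaps) == []     # unplaced
        # 1 bp of gap contact is enough for removal
        assert qc_filter([mk_call(start=48_000, end=50_001)], gaps) == []
        assert qc_filter([mk_call(start=48_000, end=50_000)], gaps) != []

    def test_size_exactly_1kb_removed(self):
        assert qc_filter([mk_call(start=10_000, end=11_000)]) == []
        assert qc_filter([mk_call(start=10_000, end=11_001)]) != []

    def test_hand_enumerated_fixture(self):
        gaps = [Interval("chr1", 100_000, 110_000)]
        calls = [
            mk_call(start=0, end=5_000),                 # keeps
            mk_call(start=6_000, end=8_000, p=0.5),      # fails p
            mk_call(start=9_000, end=9_900),             # fails size
            mk_call(start=20_000, end=30_000),           # keeps
            mk_call(start=40_000, end=45_000, q0=0.9),   # fails q0
            mk_call(start=99_000, end=100_001),          # touches gap by 1 bp
        ]
        kept = qc_filter(calls, gaps)
        assert kept == [calls[0], calls[3]]

    def test_filter_is_pure_and_order_preserving(self):
        calls = [mk_call(start=i * 10_000, end=i * 10_000 + 2_000, p=1e-4)
                 for i in range(6)]
        rev = qc_filter(list(reversed(calls)))
        assert rev == list(reversed(qc_filter(calls)))


class TestOperatingCharacteristics:
    def test_null_simulation_rarely_calls(self):
        # amplitude 0, no events: <= 1 surviving call per 50k bins over 10 seeds
        genome = GenomeSpec([Chromosome("chr1", 10_000_000)], bin_size=200)
        truth = TruthSet(genome=genome, samples=[("s1", "high")], events=[], seed=0)
        total = 0
        for seed in range(10):
            track = simulate_bins(truth, "s1", 20.0, 0.0, seed=seed)
            total += len(call_sample(track))
        assert total <= 10

    def test_planted_events_recovered_with_low_fdr(self):
        genome = make_genome(n_chroms=3, chrom_length=6_000_000)
        truth = build_truth(
            genome, n_events_per_label={lab: 12 for lab in
                                        ("shared", "high_specific",
                                         "low_specific", "private")},
            seed=21)
        tracks = simulate_cohort(truth, 20.0, 0.3)
        calls = [c for s in truth.sample_ids
                 for c in call_sample(tracks[s], genome.baseline_cn_by_chrom,
                                      genome.gaps)]
        rm = recovery_metrics(calls, truth, 0.5)
        assert rm.sensitivity >= 0.86
        assert rm.fdr <= 0.20
        assert rm.cn_exact_fraction >= 0.9
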