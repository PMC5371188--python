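"""Score the caller against planted truth: sensitivity, FDR, exact CN.

Runs a small seeded cohort, matches surviving calls to planted events
one-to-one at 50% reciprocal overlap, and reports the recovery metrics
that scripts/acceptance.py computes at full benchmark scale.
"""

from rdcnv import (build_truth, call_sample, make_genome,
                   plant_noisy_regions, recovery_metrics, simulate_cohort)

genome = make_genome(n_chroms=3, chrom_length=6_000_000)
truth = build_truth(
    genome,
    n_events_per_label={lab: 10 for lab in
                        ("shared", "high_specific", "low_specific", "private")},
    length_range=(2_000, 50_000),
    cn_choices=(0, 1, 3, 4),
    seed=1,
)
genome.noisy_regions = plant_noisy_regions(genome, n=6, seed=1,
                                           avoid=list(truth.events))
tracks = simulate_cohort(truth, lambda_per_bin=20.0, gc_bias_amplitude=0.3)

calls = [c for s in truth.sample_ids
         for c in call_sample(tracks[s], genome.baseline_cn_by_chrom,
                              genome.gaps)]

rm = recovery_metrics(calls, truth, match_threshold=0.5)
print(f"truth units (event x carrier sample): {rm.n_truth_units}")
print(f"calls after QC:                       {rm.n_calls}")
print(f"sensitivity: {100 * rm.sensitivity:.1f}%   "
      f"(fraction of planted units recovered)")
print(f"FDR:         {100 * rm.fdr:.1f}%   "
      f"(fraction of calls matching no planted unit)")
print(f"exact CN:    {100 * rm.cn_exact_fraction:.1f}%   "
      f"(matched calls whose integer CN equals the planted one)")
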