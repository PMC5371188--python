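# Methods

## Scope and data model

`rdcnv` implements a comparative CNV analysis for two-group
re-sequencing designs.  All coordinates are 0-based half-open
internally; external dialects (1-based inclusive caller text, 1-based
annotation TSVs) are converted at the boundary and must be declared
explicitly — the package never guesses a coordinate convention, because
a silent off-by-one is undetectable downstream.

The unit of coverage is the *bin*: a fixed window (default 200 bp)
carrying a read count, a GC fraction and a zero-MAPQ fraction (q0, the
proportion of reads mapped with zero mapping quality — a proxy for
repetitive sequence).  Chromosomes carry a baseline copy number:
2 for autosomes, optionally 1 for the single X of a bull.

## Synthetic cohorts

The generator emulates the motivating design: 8 samples in two groups
of 4 ("high"/"low"), ~10× coverage.  Its defaults are the study
conditions, not tuning knobs:

- **Count model.** Bin counts are Poisson with mean
  `λ · (CN/baseline) · gc_factor(gc)`.  `λ = 20` reads/bin corresponds
  to 10× coverage with 2×100 bp reads at 200 bp bins
  (`coverage_for_depth(10, 100, 200) = 20`), the middle of the 8.2–11.9×
  range the design targets.  Bins inside assembly gaps have zero
  expectation.
- **GC landscape and bias.** GC per bin is a fixed smooth function of
  position (two incommensurate sine waves around 0.45) — identical
  across samples, as real GC is.  The bias factor is
  `1 + A·cos(2π·gc)`, clipped at 0.1; amplitude `A = 0.3` is the
  simulated default, a deliberately strong bias so the correction stage
  is genuinely exercised.  Any smooth unimodal bias would do; this one
  was chosen for testability.
- **Planted events.** Labels fix the carrier set: `shared` (all 8),
  `high_specific`/`low_specific` (all and only one group), `private`
  (one sample).  All carriers of an event share one integer copy number
  drawn from {0, 1, 3, 4}.  Events are uniform in length (default
  2–50 kb), avoid gaps, and keep ≥ 10 bins (2 kb) of separation from
  one another — closer events would be merged by any bin-level caller
  by construction, so separability is made a property of the truth
  rather than an accident of the seed.
- **q0 noise.** Zero-MAPQ fractions sit at 0.05 background and 0.8
  inside designated noisy intervals.  Noisy intervals are planted
  disjoint from CNV events so the q0 filter can be tested without
  confounding recovery statistics.
- **Boundary convention.** A bin takes the copy number of the event
  covering its midpoint, keeping truth and track aligned to the grid.
- **Determinism.** Every draw flows from `numpy` `default_rng([seed,
  sample_index])`; identical inputs give byte-identical tracks.

What the simulator does *not* model: read-level artefacts (FASTQ/BAM
are out of scope), mappability structure beyond the q0 intervals,
family relatedness (the analysis uses group membership only),
dispersion beyond Poisson, and breakpoint microhomology.  Passing
benchmarks here therefore demonstrate correctness of the pipeline's
logic and its behaviour under Poisson noise with GC bias — not
performance on real libraries, where overdispersion and mappability
would raise the false-discovery rate.

## The caller

Stages: GC correction → normalisation → segmentation → calling → QC.

**GC correction.** Bins are stratified into 40 GC quantile strata; each
count is rescaled by `global_level / level(stratum)`, the levels being
5%-trimmed means over autosomal non-zero bins.  Trimmed means rather
than medians: Poisson counts are integers, so stratum medians move in
unit steps (~5% of λ at λ=20), and because GC varies smoothly along the
genome those quantisation errors are spatially correlated and generate
false segments; the trimmed mean is equally insensitive to the small
fraction of CNV bins but varies continuously.  Strata with under 100
bins fall back to no correction.  Zero-count bins (gaps, homozygous
deletions) are excluded from all reference statistics — including them
deflates the normalising mean and shifts the whole profile up by the
gap fraction, which at ~1% genome gap content is already enough to
bias duplication detection.  The corrected profile is divided by its
autosomal non-zero mean, so neutral depth is 1 by construction;
baseline-1 chromosomes are then rescaled ×2 so thresholds and
copy-number rounding operate on one scale.

**Segmentation.** Candidate segments are maximal runs of bins whose
*smoothed* depth (centred moving average, default 7 bins = 1.4 kb)
crosses 0.75 (deletion side) or 1.25 (duplication side) — the midpoints
between copy numbers 1/2 and 2/3 on the normalised scale.  Smoothing is
the multi-bin statistic: a single 200 bp bin at λ=20 has sd ≈ 0.22 of
its mean, so raw-bin thresholding both fragments copy-number-3 events
and crosses thresholds by chance in long clusters.  Runs may bridge up
to 5 interior bins (1 kb) that fall back into the neutral band —
smoothed excursions are autocorrelated over the window width, so a
single noise dip spans several positions; the bridge stays below the
generator's 2 kb event separation so distinct events cannot fuse.
A bin on the *opposite* side of neutral never bridges.  Finally a run
must be confirmed by its **raw-bin mean** reaching 0.65 / 1.35 (midway
between the enter threshold and a true one-copy change at 0.5 / 1.5).
The confirmation is the false-positive control: runs are selected by
thresholding, so any significance test applied to them is passed by
construction, and only effect size separates a chance excursion
(mean just past 1.25) from a real gain (mean near 1.5).  Measured on
the Poisson model, the defaults give ≈ 0.1 surviving false calls per
50,000 bins with no GC bias and ≈ 1.3 with amplitude-0.3 bias after
correction.

**Calling.** One call per segment: mean raw corrected depth (RD), type
deletion iff RD < 1, integer copy number `max(0, round(baseline·RD))`
(half away from zero), p-value from a two-sided one-sample t-test of
the segment's raw bins against 1 (a 1-bin or zero-variance-at-1
segment gets p = 1 and can never pass QC; a zero-variance segment away
from 1, e.g. all-zero bins of a homozygous deletion, gets p = 0), and
q0 as the unweighted bin mean (bins are equal width, so this is the
length-weighted mean).

**QC.** Retained: p < 0.01 and length > 1 kb (strictly — exactly
1000 bp fails) and q0 < 0.5 and zero bases of overlap with any assembly
gap and chromosome not in the drop list (`chrUn` by default).  The
filter is a pure, order-preserving function.

## CNVR algebra

- *Common CNVs* (within a group): a call qualifies if any call from a
  different individual overlaps it reciprocally by **strictly more
  than** the threshold (default 0.30) in both directions.  Partner
  calls must match in type by default (a deletion and a duplication at
  one locus are different events); this is configurable off.
- *Merging*: transitive closure under ≥ 1 bp overlap (half-open
  intervals — abutting regions share 0 bp and do not merge).  Merged
  regions span component min(start)–max(end) and aggregate samples,
  groups and category (`both` when deletions and duplications mix).
- *Shared vs specific*: a group's CNVR is shared when it matches any
  CNVR of the other group under the same strict-reciprocal criterion;
  the ≥ 1 bp alternative is available (`shared_criterion: overlap`)
  since between-group matching is a genuinely open design point.  The
  three outputs partition the inputs.
- *Differential CNVRs*: the two group-specific sets merged at ≥ 1 bp.

"Whole CNVRs of a group" is interpreted as that group's common-CNVR
set; the pipeline performs the split directly on the two common-CNVR
sets (the only per-group CNVR sets the procedure defines).

## Annotation, summaries, qPCR

Feature overlap is ≥ 1 bp by default ("completely or partially"
contained genes count); strand is carried but ignored — CNVs are
unstranded.  Gene/QTL tables are read as BED or 1-based TSV under an
explicit dialect flag.

Length statistics are reported in kb (totals in Mb), standard deviation
in sample (n−1) form by default with the convention recorded in the
output.  Size histograms use [lo, hi) bins in kb with an explicit
underflow bin.  Recovery metrics match calls to planted (event ×
carrier sample) units one-to-one, greedily by descending overlap with
leftmost tie-break, at a reciprocal-overlap threshold (default 0.5);
FDR with zero calls is reported as 0 with a flag rather than NaN.

qPCR: replicate Cts are averaged arithmetically (no outlier rejection);
copies = `2·2^−ΔΔCt`; gain/loss thresholds are inclusive hard cutoffs
at 3.0/1.0 — the natural reading of "around 3 or above / around 1 or
below" as an operational rule — and configurable.  A predicted-normal
region confirmed normal counts as concordant.  Efficiency-corrected
ΔΔCt variants are out of scope.

## Problem sizes

The benchmark in `scripts/acceptance.py` uses five seeded cohorts of
8 samples on a 5 × 10 Mb genome (250k bins/sample) with 120 planted
events each — large enough that sensitivity and FDR are estimated from
~2,500 truth units and ~2,800 calls, small enough to run in seconds.
The unit suite uses 2–18 Mb genomes.  Scaling to a full mammalian
genome is linear in bins; nothing in the implementation assumes the
benchmark sizes.

## Known limitations

- Significance (pval1) is nearly uninformative after threshold
  selection; it is retained for fidelity to the filtering convention,
  but the effect-size confirmation is what controls false discovery.
- Breakpoints are bin-resolution; no sub-bin refinement, no split-read
  evidence, no multi-bin-size ensemble.
- The Poisson model understates real-library variance; on real data the
  confirmation thresholds and q0 filter would need re-examination
  against overdispersion and mappability tracks.
- Baseline-1 chromosomes are handled by rescaling; hemizygous CNV
  calling on X is mechanically supported but untuned (a single-copy
  gain on X moves depth from 0.5→1.0 of autosomal level, i.e. appears
  as 1.0→2.0 after rescaling).
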