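"""Synthetic cohorts of binned read-depth tracks with planted CNV truth.

The generator emulates a two-group re-sequencing design: eight bulls in a
high and a low phenotype group (4 vs 4), ~10x coverage summarised as
Poisson-distributed read counts per fixed-width genomic bin.  CNVs are
planted as integer copy-number changes that are shared by the whole
cohort, specific to one group, or private to one sample, and the exact
truth is exportable for recovery benchmarking.

The count model: a bin with local copy number ``cn`` on a chromosome with
baseline copy number ``b`` has expected count

    lambda_per_bin * (cn / b) * gc_factor(gc)

and the observed count is Poisson with that mean.  GC content varies
smoothly along the genome; the GC bias factor is
``1 + amplitude * cos(2*pi*gc)`` clipped below at 0.1 — a smooth unimodal
bias that the caller's GC-correction stage must remove.  Zero-MAPQ
fractions sit at a background level except inside designated noisy
intervals, which stand in for repeat-rich sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import Chromosome, GenomeSpec, Interval

LABELS = ("shared", "high_specific", "low_specific", "private")
GROUPS = ("high", "low")


class PlacementError(RuntimeError):
    """Raised when a planted event cannot be placed on the genome."""


@dataclass(frozen=True)
class PlantedCnv:
    """One planted CNV: an interval plus per-sample integer copy numbers."""

    chrom: str
    start: int
    end: int
    cn_by_sample: Mapping[str, int]
    label: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("planted CNV must span at least one base")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        object.__setattr__(self, "cn_by_sample", dict(self.cn_by_sample))

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    """A cohort design plus the full list of planted events."""

    genome: GenomeSpec
    samples: list[tuple[str, str]]  # (sample_id, group)
    events: list[PlantedCnv]
    seed: int

    def __post_init__(self) -> None:
        groups = {g for _, g in self.samples}
        if groups - set(GROUPS):
            raise ValueError(f"unknown groups {groups - set(GROUPS)}")
        ids = [s for s, _ in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        known = set(ids)
        for ev in self.events:
            extra = set(ev.cn_by_sample) - known
            if extra:
                raise ValueError(f"event carriers {extra} not in cohort")

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]

    def group_of(self, sample_id: str) -> str:
        for s, g in self.samples:
            if s == sample_id:
                return g
        raise KeyError(sample_id)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.samples if g == group]


@dataclass
class ChromBins:
    """Per-chromosome bin arrays of one sample's track."""

    counts: np.ndarray  # non-negative int
    gc: np.ndarray      # fraction in [0, 1]
    q0: np.ndarray      # fraction in [0, 1]


@dataclass
class BinTrack:
    """One sample's binned read-depth track."""

    sample_id: str
    bin_size: int
    chroms: dict[str, ChromBins] = field(default_factory=dict)

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chroms)

    def n_bins(self, chrom: str) -> int:
        return len(self.chroms[chrom].counts)


def make_genome(
    n_chroms: int = 5,
    chrom_length: int = 10_000_000,
    bin_size: int = 200,
    gaps_per_chrom: int = 2,
    gap_length: int = 50_000,
) -> GenomeSpec:
    """A plain autosomal genome with gaps at fixed fractional positions."""
    chroms = [Chromosome(f"chr{i + 1}", chrom_length) for i in range(n_chroms)]
    gaps = []
    fracs = [0.33, 0.71, 0.12, 0.55, 0.88][:gaps_per_chrom]
    for c in chroms:
        for f in fracs:
            start = int(c.length * f) // bin_size * bin_size
            gaps.append(Interval(c.name, start, start + gap_length))
    return GenomeSpec(chroms, bin_size=bin_size, gaps=gaps)


def _intersects_any(chrom: str, start: int, end: int,
                    intervals: Iterable[Interval], margin: int = 0) -> bool:
    for iv in intervals:
        if iv.chrom == chrom and min(end + margin, iv.end) > max(start - margin, iv.start):
            return True
    return False


def coverage_for_depth(depth: float, read_length: float, bin_size: float) -> float:
    """Expected reads per bin for a given fold coverage.

    ``depth`` x coverage with reads of ``read_length`` bp places
    ``depth * bin_size / read_length`` read starts in a ``bin_size`` bin.
    """
    if depth < 0 or read_length <= 0 or bin_size <= 0:
        raise ValueError("depth must be >= 0; read_length and bin_size > 0")
    return depth * bin_size / read_length


def build_truth(
    genome: GenomeSpec,
    n_per_group: int = 4,
    n_events_per_label: Mapping[str, int] | None = None,
    length_range: tuple[int, int] = (2_000, 50_000),
    cn_choices: Sequence[int] = (0, 1, 3, 4),
    seed: int = 0,
    min_separation: int | None = None,
    max_tries: int = 1_000,
) -> TruthSet:
    """Plant labelled CNV events on a genome for a 2-group cohort.

    Events are pairwise non-overlapping (separated by at least
    ``min_separation`` bp, default 10 bins, so that neighbouring events
    are resolvable by a bin-level caller), avoid assembly gaps, and carry
    the same non-baseline copy number in every carrier sample.  Carriers
    follow the label: ``shared`` alters all samples, ``high_specific`` /
    ``low_specific`` all and only the samples of that group, ``private``
    a single sample.
    """
    if n_events_per_label is None:
        n_events_per_label = {lab: 0 for lab in LABELS}
    unknown = set(n_events_per_label) - set(LABELS)
    if unknown:
        raise ValueError(f"unknown labels {unknown}")
    lo, hi = length_range
    if lo < 2 * genome.bin_size:
        raise ValueError("length_range minimum must be >= 2 bins")
    if hi < lo:
        raise ValueError("length_range must be (min, max) with min <= max")
    if not cn_choices:
        raise ValueError("cn_choices must be non-empty")
    if min_separation is None:
        min_separation = 10 * genome.bin_size

    rng = np.random.default_rng(seed)
    samples = [(f"high{i + 1}", "high") for i in range(n_per_group)] + \
              [(f"low{i + 1}", "low") for i in range(n_per_group)]
    by_group = {
        "high": [s for s, g in samples if g == "high"],
        "low": [s for s, g in samples if g == "low"],
    }

    chrom_names = genome.chrom_names
    weights = np.array([genome.length_of(c) for c in chrom_names], dtype=float)
    weights /= weights.sum()

    placed: list[Interval] = []
    events: list[PlantedCnv] = []
    for label in LABELS:  # fixed order keeps the draw sequence deterministic
        for _ in range(int(n_events_per_label.get(label, 0))):
            length = int(rng.integers(lo, hi + 1))
            for _try in range(max_tries):
                chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
                clen = genome.length_of(chrom)
                if clen <= length:
                    continue
                start = int(rng.integers(0, clen - length))
                end = start + length
                if _intersects_any(chrom, start, end, genome.gaps):
                    continue
                if _intersects_any(chrom, start, end, placed, margin=min_separation):
                    continue
                break
            else:
                raise PlacementError(
                    f"could not place a {label} event of {length} bp "
                    f"after {max_tries} tries"
                )
            baseline = genome.baseline_cn(chrom)
            choices = [c for c in cn_choices if c != baseline]
            if not choices:
                raise ValueError("cn_choices offers no non-baseline copy number")
            cn = int(choices[rng.integers(0, len(choices))])
            if label == "shared":
                carriers = [s for s, _ in samples]
            elif label == "high_specific":
                carriers = by_group["high"]
            elif label == "low_specific":
                carriers = by_group["low"]
            else:
                carriers = [samples[rng.integers(0, len(samples))][0]]
            placed.append(Interval(chrom, start, end))
            events.append(PlantedCnv(chrom, start, end,
                                     {s: cn for s in carriers}, label))

    events.sort(key=lambda e: (e.chrom, e.start, e.end))
    return TruthSet(genome=genome, samples=samples, events=events, seed=seed)


def plant_noisy_regions(
    genome: GenomeSpec,
    n: int,
    length: int = 100_000,
    seed: int = 0,
    avoid: Iterable[Interval] = (),
) -> list[Interval]:
    """Place intervals of elevated zero-MAPQ fraction, avoiding ``avoid``.

    Kept disjoint from planted events so the q0 QC filter can be tested
    without confounding recovery of the events themselves.
    """
    rng = np.random.default_rng(seed)
    avoid = list(avoid)
    chrom_names = genome.chrom_names
    out: list[Interval] = []
    for _ in range(n):
        for _try in range(1_000):
            chrom = chrom_names[rng.integers(0, len(chrom_names))]
            clen = genome.length_of(chrom)
            if clen <= length:
                continue
            start = int(rng.integers(0, clen - length)) // genome.bin_size
            start *= genome.bin_size
            end = start + length
            if _intersects_any(chrom, start, end, avoid) or \
               _intersects_any(chrom, start, end, out):
                continue
            out.append(Interval(chrom, start, end))
            break
        else:
            raise PlacementError(f"could not place noisy region of {length} bp")
    return sorted(out)


def _gc_profile(midpoints: np.ndarray) -> np.ndarray:
    # Deterministic smooth GC landscape: two incommensurate waves around 0.45.
    gc = (0.45
          + 0.08 * np.sin(2 * math.pi * midpoints / 1.5e6)
          + 0.04 * np.sin(2 * math.pi * midpoints / 2.37e5))
    return np.clip(gc, 0.0, 1.0)


def gc_factor(gc: np.ndarray | float, amplitude: float) -> np.ndarray | float:
    """Smooth unimodal GC bias on the expected count; clipped at 0.1."""
    return np.maximum(1.0 + amplitude * np.cos(2 * math.pi * np.asarray(gc, dtype=float)), 0.1)


def simulate_bins(
    truth: TruthSet,
    sample: str,
    lambda_per_bin: float = 20.0,
    gc_bias_amplitude: float = 0.0,
    q0_levels: tuple[float, float] = (0.05, 0.8),
    seed: int = 0,
) -> BinTrack:
    """Draw one sample's binned read counts from the Poisson count model.

    A bin takes the copy number of the planted event covering its
    midpoint (baseline otherwise); bins inside assembly gaps have zero
    expected coverage.  Deterministic for fixed (truth, sample,
    parameters, seed); different samples of the same cohort get
    independent streams.
    """
    if lambda_per_bin <= 0:
        raise ValueError("lambda_per_bin must be > 0")
    if seed < 0:
        raise ValueError("seed must be >= 0")
    ids = truth.sample_ids
    if sample not in ids:
        raise KeyError(f"unknown sample {sample!r}")
    if gc_bias_amplitude < 0:
        raise ValueError("gc_bias_amplitude must be >= 0")
    rng = np.random.default_rng([seed, ids.index(sample)])
    genome = truth.genome
    bs = genome.bin_size
    q0_background, q0_elevated = q0_levels

    track = BinTrack(sample_id=sample, bin_size=bs)
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        mid = np.arange(n, dtype=np.int64) * bs + bs // 2
        gc = _gc_profile(mid)
        baseline = genome.baseline_cn(chrom)

        cn = np.full(n, baseline, dtype=float)
        for ev in truth.events:
            if ev.chrom != chrom or sample not in ev.cn_by_sample:
                continue
            i0 = int(np.searchsorted(mid, ev.start, side="left"))
            i1 = int(np.searchsorted(mid, ev.end, side="left"))
            cn[i0:i1] = ev.cn_by_sample[sample]

        expected = lambda_per_bin * (cn / baseline) * gc_factor(gc, gc_bias_amplitude)
        for gap in genome.gaps:
            if gap.chrom != chrom:
                continue
            i0 = int(np.searchsorted(mid, gap.start, side="left"))
            i1 = int(np.searchsorted(mid, gap.end, side="left"))
            expected[i0:i1] = 0.0
        counts = rng.poisson(expected)

        q0 = np.clip(q0_background + rng.normal(0.0, 0.02, n), 0.0, 1.0)
        for noisy in genome.noisy_regions:
            if noisy.chrom != chrom:
                continue
            i0 = int(np.searchsorted(mid, noisy.start, side="left"))
            i1 = int(np.searchsorted(mid, noisy.end, side="left"))
            q0[i0:i1] = np.clip(q0_elevated + rng.normal(0.0, 0.02, i1 - i0), 0.0, 1.0)

        track.chroms[chrom] = ChromBins(counts=counts, gc=gc, q0=q0)
    return track


def simulate_cohort(
    truth: TruthSet,
    lambda_per_bin: float = 20.0,
    gc_bias_amplitude: float = 0.3,
    q0_levels: tuple[float, float] = (0.05, 0.8),
    seed: int | None = None,
) -> dict[str, BinTrack]:
    """Tracks for every sample of the cohort (seed defaults to the truth's)."""
    if seed is None:
        seed = truth.seed
    return {
        s: simulate_bins(truth, s, lambda_per_bin, gc_bias_amplitude, q0_levels, seed)
        for s in truth.sample_ids
    }
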