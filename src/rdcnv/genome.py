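"""Genome model shared by the simulator and the caller.

All coordinates in this package are 0-based, half-open, in base pairs.
A genome is a list of named chromosomes with a per-chromosome baseline
copy number (2 for autosomes; 1 may be used for the single X of a bull),
a fixed bin width for read-depth tracks, assembly gaps, and optional
"noisy" intervals in which the simulator elevates the zero-MAPQ fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "Interval") -> int:
        """Shared bases with ``other``; 0 when disjoint or on another chromosome."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def overlap_bp(a, b) -> int:
    """Shared bases between two objects carrying chrom/start/end."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    baseline_cn: int = 2

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if self.baseline_cn not in (1, 2):
            raise ValueError(
                f"chromosome {self.name}: baseline_cn must be 1 or 2"
            )


@dataclass
class GenomeSpec:
    """Chromosome sizes, bin width, gaps and noisy intervals.

    Chromosome lengths are truncated to a whole number of bins on
    construction so that bin arrays tile the genome exactly.
    """

    chromosomes: list[Chromosome]
    bin_size: int = 200
    gaps: list[Interval] = field(default_factory=list)
    noisy_regions: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        self.chromosomes = [
            replace(c, length=(c.length // self.bin_size) * self.bin_size)
            for c in self.chromosomes
        ]
        lengths = {c.name: c.length for c in self.chromosomes}
        for label, ivs in (("gap", self.gaps), ("noisy region", self.noisy_regions)):
            for iv in ivs:
                if iv.chrom not in lengths:
                    raise ValueError(f"{label} on unknown chromosome {iv.chrom}")
                if iv.end > lengths[iv.chrom]:
                    raise ValueError(
                        f"{label} {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {lengths[iv.chrom]}"
                    )

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chrom(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def length_of(self, name: str) -> int:
        return self.chrom(name).length

    def baseline_cn(self, name: str) -> int:
        return self.chrom(name).baseline_cn

    def n_bins(self, name: str) -> int:
        return self.length_of(name) // self.bin_size

    @property
    def baseline_cn_by_chrom(self) -> dict[str, int]:
        return {c.name: c.baseline_cn for c in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)
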