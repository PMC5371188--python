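"""CNVR interval algebra: common CNVs, merging, and differential regions.

The case–control procedure implemented here:

1. within each phenotype group, a call is a *common CNV* if some call
   from a different individual of the group reciprocally overlaps it by
   strictly more than 30% (both fractions);
2. common CNVs are merged into *common CNV regions* (CNVRs) whenever
   they share at least 1 bp, transitively;
3. CNVRs shared between the high and low group (same reciprocal
   criterion by default) are removed from each group's set, leaving
   group-specific CNVRs;
4. the union of the two group-specific sets, merged again at >= 1 bp,
   forms the *differential CNVRs*, each categorised as deletion,
   duplication or both from its contributing calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .caller import DELETION, DUPLICATION, CnvCall
from .genome import overlap_bp

CATEGORY_BOTH = "both"


@dataclass(frozen=True)
class Cnvr:
    """A merged CNV region across samples."""

    chrom: str
    start: int
    end: int
    category: str  # "deletion" | "duplication" | "both"
    samples: frozenset[str] = frozenset()
    groups: frozenset[str] = frozenset()
    source_calls: tuple = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("CNVR must span at least one base")
        if self.category not in (DELETION, DUPLICATION, CATEGORY_BOTH):
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def reciprocal_overlap(a, b) -> tuple[float, float]:
    """Overlap length divided by each interval's length.

    Returns (fraction_of_a, fraction_of_b); (0, 0) when disjoint or on
    different chromosomes.  Intervals are 0-based half-open objects with
    chrom/start/end; zero-length intervals are rejected.
    """
    la, lb = a.end - a.start, b.end - b.start
    if la <= 0 or lb <= 0:
        raise ValueError("zero-length interval")
    ov = overlap_bp(a, b)
    return ov / la, ov / lb


def _types_of(item) -> set[str]:
    if isinstance(item, Cnvr):
        return {DELETION, DUPLICATION} if item.category == CATEGORY_BOTH else {item.category}
    return {item.type}


def _samples_of(item) -> set[str]:
    if isinstance(item, Cnvr):
        return set(item.samples)
    return {item.sample_id}


def _groups_of(item, group_by_sample: Mapping[str, str] | None) -> set[str]:
    if isinstance(item, Cnvr):
        return set(item.groups)
    if group_by_sample and item.sample_id in group_by_sample:
        return {group_by_sample[item.sample_id]}
    return set()


def _sources_of(item) -> tuple:
    if isinstance(item, Cnvr):
        return tuple(item.source_calls)
    return (item,)


def find_common_cnvs(
    calls_by_individual: Mapping[str, Sequence[CnvCall]],
    threshold: float = 0.3,
    require_same_type: bool = True,
) -> set[CnvCall]:
    """Calls with a cross-individual partner at > threshold reciprocal overlap.

    Symmetric: a call qualifies iff one of its partners does.  The
    threshold is strict — exactly 30% does not qualify.  By default a
    deletion can only partner a deletion, a duplication a duplication.
    """
    entries: list[tuple[str, CnvCall]] = [
        (indiv, call)
        for indiv, calls in calls_by_individual.items()
        for call in calls
    ]
    trees: dict[str, IntervalTree] = {}
    for indiv, call in entries:
        trees.setdefault(call.chrom, IntervalTree()).addi(call.start, call.end, (indiv, call))

    common: set[CnvCall] = set()
    for indiv, call in entries:
        if call in common:
            continue
        for hit in trees[call.chrom].overlap(call.start, call.end):
            other_indiv, other = hit.data
            if other_indiv == indiv:
                continue
            if require_same_type and other.type != call.type:
                continue
            fa, fb = reciprocal_overlap(call, other)
            if fa > threshold and fb > threshold:
                common.add(call)
                common.add(other)
                break
    return common


def merge_cnvs(
    calls: Iterable,
    min_overlap_bp: int = 1,
    group_by_sample: Mapping[str, str] | None = None,
) -> list[Cnvr]:
    """Merge calls (or CNVRs) overlapping by >= min_overlap_bp into CNVRs.

    Merging is transitive: chains A–B, B–C collapse into one region even
    if A and C are disjoint.  Each output region spans min(start) to
    max(end) of its components and aggregates samples, groups and the
    deletion/duplication category ("both" when mixed).  Outputs are
    sorted and pairwise overlap by less than min_overlap_bp.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    items = sorted(calls, key=lambda c: (c.chrom, c.start, c.end))
    out: list[Cnvr] = []
    cluster: list = []
    cur_chrom, cur_end = None, 0

    def flush() -> None:
        if not cluster:
            return
        types: set[str] = set()
        samples: set[str] = set()
        groups: set[str] = set()
        sources: list = []
        for it in cluster:
            types |= _types_of(it)
            samples |= _samples_of(it)
            groups |= _groups_of(it, group_by_sample)
            sources.extend(_sources_of(it))
        category = CATEGORY_BOTH if len(types) == 2 else next(iter(types))
        out.append(Cnvr(
            chrom=cur_chrom,
            start=min(it.start for it in cluster),
            end=cur_end,
            category=category,
            samples=frozenset(samples),
            groups=frozenset(groups),
            source_calls=tuple(sources),
        ))

    for it in items:
        if cluster and it.chrom == cur_chrom and cur_end - it.start >= min_overlap_bp:
            cluster.append(it)
            cur_end = max(cur_end, it.end)
        else:
            flush()
            cluster = [it]
            cur_chrom, cur_end = it.chrom, it.end
    flush()
    return out


def group_common_cnvrs(
    group_calls: Mapping[str, Sequence[CnvCall]],
    threshold: float = 0.3,
    group_name: str | None = None,
    min_overlap_bp: int = 1,
    require_same_type: bool = True,
) -> list[Cnvr]:
    """One group's common CNVRs: common CNVs merged at >= min_overlap_bp."""
    common = find_common_cnvs(group_calls, threshold, require_same_type)
    ordered = sorted(common, key=lambda c: (c.chrom, c.start, c.end, c.sample_id, c.type))
    gbs = {c.sample_id: group_name for c in ordered} if group_name else None
    return merge_cnvs(ordered, min_overlap_bp, group_by_sample=gbs)


def _is_shared(cnvr: Cnvr, others: Sequence[Cnvr], criterion: str,
               threshold: float, min_overlap_bp: int) -> bool:
    for o in others:
        if o.chrom != cnvr.chrom:
            continue
        if criterion == "reciprocal":
            fa, fb = reciprocal_overlap(cnvr, o)
            if fa > threshold and fb > threshold:
                return True
        elif criterion == "overlap":
            if overlap_bp(cnvr, o) >= min_overlap_bp:
                return True
        else:
            raise ValueError(f"unknown shared criterion {criterion!r}")
    return False


def split_shared_specific(
    high_cnvrs: Sequence[Cnvr],
    low_cnvrs: Sequence[Cnvr],
    criterion: str = "reciprocal",
    threshold: float = 0.3,
    min_overlap_bp: int = 1,
) -> tuple[list[Cnvr], list[Cnvr], list[Cnvr]]:
    """Partition each group's CNVRs into shared vs group-specific.

    A CNVR is shared when it matches any CNVR of the other group under
    the chosen criterion ("reciprocal": both fractions > threshold;
    "overlap": >= min_overlap_bp shared bases).  Returns (shared,
    high_specific, low_specific); the three lists partition the inputs.
    """
    shared: list[Cnvr] = []
    high_specific: list[Cnvr] = []
    low_specific: list[Cnvr] = []
    for c in high_cnvrs:
        (shared if _is_shared(c, low_cnvrs, criterion, threshold, min_overlap_bp)
         else high_specific).append(c)
    for c in low_cnvrs:
        (shared if _is_shared(c, high_cnvrs, criterion, threshold, min_overlap_bp)
         else low_specific).append(c)
    return shared, high_specific, low_specific


def differential_cnvrs(
    high_specific: Sequence[Cnvr],
    low_specific: Sequence[Cnvr],
    min_overlap_bp: int = 1,
) -> list[Cnvr]:
    """Merge the two group-specific sets into differential CNVRs."""
    return merge_cnvs(list(high_specific) + list(low_specific), min_overlap_bp)
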