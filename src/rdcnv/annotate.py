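"""Overlap of CNVRs with gene and QTL annotation intervals.

A feature "hits" a CNVR when they share at least ``min_overlap_bp``
bases — complete or partial containment both count.  CNVs are
unstranded, so strand is carried through but never used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .genome import overlap_bp


@dataclass(frozen=True)
class AnnotationRecord:
    """A gene or QTL interval, 0-based half-open after input conversion."""

    chrom: str
    start: int
    end: int
    id: str
    name: str = ""
    kind: str = "gene"  # "gene" | "qtl"
    attribute: str = ""  # biotype or trait
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty feature {self.id}")
        if self.kind not in ("gene", "qtl"):
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_features(
    cnvrs: Sequence,
    features: Sequence[AnnotationRecord],
    min_overlap_bp: int = 1,
) -> list[tuple]:
    """Every (cnvr, feature) pair sharing >= min_overlap_bp bases.

    Each qualifying pair is reported exactly once with its exact overlap
    in bp; output order is by CNVR coordinate then feature id, so the
    result is invariant under input reordering.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    out: list[tuple] = []
    for cnvr in sorted(cnvrs, key=lambda c: (c.chrom, c.start, c.end)):
        tree = trees.get(cnvr.chrom)
        if tree is None:
            continue
        hits = []
        for hit in tree.overlap(cnvr.start, cnvr.end):
            f = hit.data
            ov = overlap_bp(cnvr, f)
            if ov >= min_overlap_bp:
                hits.append((f.id, f, ov))
        for _, f, ov in sorted(hits, key=lambda h: h[0]):
            out.append((cnvr, f, ov))
    return out


def summarize_gene_coverage(
    cnvrs: Sequence,
    genes: Sequence[AnnotationRecord],
    min_overlap_bp: int = 1,
) -> tuple[int, float, int]:
    """(CNVRs with >= 1 gene, fraction of CNVRs, distinct genes hit)."""
    pairs = overlap_features(cnvrs, genes, min_overlap_bp)
    hit_cnvrs = {(c.chrom, c.start, c.end) for c, _, _ in pairs}
    distinct = {f.id for _, f, _ in pairs}
    n = len(hit_cnvrs)
    frac = n / len(cnvrs) if cnvrs else 0.0
    return n, frac, len(distinct)
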