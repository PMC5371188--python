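"""Descriptive statistics and truth-based recovery metrics.

Length statistics are reported in kb (totals in Mb) to match the usual
presentation of CNVR tables; recovery metrics score calls against a
planted truth set by one-to-one best reciprocal overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .caller import DELETION, DUPLICATION, CnvCall
from .genome import overlap_bp
from .regions import CATEGORY_BOTH
from .simulate import TruthSet


@dataclass(frozen=True)
class LengthStats:
    n: int
    mean_kb: float
    median_kb: float
    min_kb: float
    max_kb: float
    std_kb: float
    total_mb: float
    ddof: int  # 1 = sample standard deviation, 0 = population


def length_stats(regions: Sequence, ddof: int = 1) -> LengthStats:
    """Length statistics of intervals, in kb (total in Mb)."""
    if not regions:
        raise ValueError("length_stats of an empty region set")
    kb = np.array([(r.end - r.start) for r in regions], dtype=float) / 1e3
    std = float(np.std(kb, ddof=ddof)) if len(kb) > ddof else 0.0
    return LengthStats(
        n=len(kb),
        mean_kb=float(kb.mean()),
        median_kb=float(np.median(kb)),
        min_kb=float(kb.min()),
        max_kb=float(kb.max()),
        std_kb=std,
        total_mb=float(kb.sum() / 1e3),
        ddof=ddof,
    )


def size_histogram(regions: Sequence,
                   breaks_kb: Sequence[float] = (1, 5, 10, 20, 50, 100),
                   ) -> dict[str, float]:
    """Fraction of regions per size bin; bins are [lo, hi) in kb.

    Regions below the first break fall in an explicit "<first" underflow
    bin; the last bin is open-ended.  Fractions sum to 1.
    """
    breaks = list(breaks_kb)
    if not breaks:
        raise ValueError("breaks must be non-empty")
    if any(b <= a for a, b in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be strictly ascending")
    if not regions:
        raise ValueError("size_histogram of an empty region set")
    kb = np.array([(r.end - r.start) for r in regions], dtype=float) / 1e3
    edges = [-math.inf] + breaks + [math.inf]
    labels = [f"<{breaks[0]:g}"] + [
        f"[{a:g},{b:g})" for a, b in zip(breaks, breaks[1:])
    ] + [f">={breaks[-1]:g}"]
    counts, _ = np.histogram(kb, bins=edges)
    fracs = counts / counts.sum()
    return dict(zip(labels, fracs.tolist()))


@dataclass(frozen=True)
class CategoryCounts:
    n_deletion: int
    n_duplication: int
    n_both: int
    deletion_mb: float
    duplication_mb: float
    both_mb: float


def category_counts(cnvrs: Sequence) -> CategoryCounts:
    """Counts and total length (Mb) per CNVR category."""
    n = {DELETION: 0, DUPLICATION: 0, CATEGORY_BOTH: 0}
    bp = {DELETION: 0, DUPLICATION: 0, CATEGORY_BOTH: 0}
    for c in cnvrs:
        n[c.category] += 1
        bp[c.category] += c.end - c.start
    return CategoryCounts(
        n_deletion=n[DELETION], n_duplication=n[DUPLICATION], n_both=n[CATEGORY_BOTH],
        deletion_mb=bp[DELETION] / 1e6, duplication_mb=bp[DUPLICATION] / 1e6,
        both_mb=bp[CATEGORY_BOTH] / 1e6,
    )


def per_sample_counts(calls: Sequence[CnvCall]) -> pd.DataFrame:
    """Tally of duplication and deletion calls per sample."""
    rows: dict[str, dict[str, int]] = {}
    for c in calls:
        row = rows.setdefault(c.sample_id, {"n_duplication": 0, "n_deletion": 0})
        row["n_duplication" if c.type == DUPLICATION else "n_deletion"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if df.empty:
        df = pd.DataFrame(columns=["n_duplication", "n_deletion"], dtype=int)
    df.index.name = "sample"
    return df.sort_index()


def coverage_depth(n_mapped_reads: float, read_length: float,
                   genome_length: float) -> float:
    """Fold coverage: mapped reads x read length / genome length."""
    if n_mapped_reads < 0 or read_length <= 0 or genome_length <= 0:
        raise ValueError("reads >= 0; read_length and genome_length > 0")
    return n_mapped_reads * read_length / genome_length


@dataclass(frozen=True)
class RecoveryMetrics:
    sensitivity: float
    fdr: float
    cn_exact_fraction: float | None  # None when calls carry no CN estimate
    n_truth_units: int
    n_calls: int
    fdr_defined: bool  # False when there were no calls at all


def _min_ro(a, b) -> float:
    ov = overlap_bp(a, b)
    return min(ov / (a.end - a.start), ov / (b.end - b.start)) if ov else 0.0


def _match_one_to_one(truth_items: list, call_items: list,
                      threshold: float) -> list[tuple[int, int]]:
    """Greedy one-to-one matching by descending overlap, ties leftmost."""
    cand = []
    for i, t in enumerate(truth_items):
        for j, c in enumerate(call_items):
            if c.chrom != t.chrom:
                continue
            if _min_ro(t, c) >= threshold:
                cand.append((-overlap_bp(t, c), t.chrom, t.start, c.start, i, j))
    cand.sort()
    used_t: set[int] = set()
    used_c: set[int] = set()
    pairs = []
    for _, _, _, _, i, j in cand:
        if i in used_t or j in used_c:
            continue
        used_t.add(i)
        used_c.add(j)
        pairs.append((i, j))
    return pairs


def recovery_metrics(
    calls_or_cnvrs: Sequence,
    truth: TruthSet,
    match_threshold: float = 0.5,
) -> RecoveryMetrics:
    """Sensitivity, FDR and exact-CN fraction against a planted truth.

    When the inputs are per-sample calls, the truth units are (event,
    carrier sample) pairs and matching is done within each sample; when
    they are sample-less regions (CNVRs), truth units are the event
    intervals.  Matching is one-to-one best reciprocal overlap at
    ``match_threshold``.  With no calls at all, FDR is reported as 0
    with ``fdr_defined=False``.
    """
    if not truth.events:
        raise ValueError("empty truth set: sensitivity undefined")
    items = list(calls_or_cnvrs)
    per_sample = bool(items) and all(
        getattr(it, "sample_id", None) is not None for it in items
    ) and not any(isinstance(getattr(it, "samples", None), frozenset) for it in items)

    matched = 0
    cn_exact = 0
    n_calls = len(items)
    n_matched_calls = 0

    if per_sample or not items:
        units = [
            (ev, sid, cn)
            for ev in truth.events
            for sid, cn in sorted(ev.cn_by_sample.items())
            if cn != truth.genome.baseline_cn(ev.chrom)
        ]
        n_truth = len(units)
        by_sample_calls: dict[str, list] = {}
        for it in items:
            by_sample_calls.setdefault(it.sample_id, []).append(it)
        for sid in sorted(by_sample_calls):
            t_units = [(ev, cn) for ev, s, cn in units if s == sid]
            calls = by_sample_calls[sid]
            pairs = _match_one_to_one([ev for ev, _ in t_units], calls, match_threshold)
            matched += len(pairs)
            n_matched_calls += len(pairs)
            for i, j in pairs:
                if getattr(calls[j], "estimated_cn", None) == t_units[i][1]:
                    cn_exact += 1
        cn_frac = (cn_exact / matched) if matched else 0.0
    else:
        t_items = truth.events
        n_truth = len(t_items)
        pairs = _match_one_to_one(list(t_items), items, match_threshold)
        matched = len(pairs)
        n_matched_calls = matched
        cn_frac = None

    sensitivity = matched / n_truth
    if n_calls:
        fdr = (n_calls - n_matched_calls) / n_calls
        defined = True
    else:
        fdr, defined = 0.0, False
    return RecoveryMetrics(
        sensitivity=sensitivity,
        fdr=fdr,
        cn_exact_fraction=cn_frac,
        n_truth_units=n_truth,
        n_calls=n_calls,
        fdr_defined=defined,
    )
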