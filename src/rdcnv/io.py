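"""Readers and writers for the package's text formats.

Internal coordinates are uniformly 0-based half-open.  Every external
dialect that differs (the caller-dialect call text and 1-based
annotation TSVs are 1-based inclusive) is converted on input and the
dialect is always declared by the caller — never inferred from file
content.  All writers produce plain TSV/CSV; paths ending in ``.gz``
are transparently gzip-compressed.  Floats are written with ``repr`` so
that write/read round-trips are exact.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotate import AnnotationRecord
from .caller import DELETION, DUPLICATION, CnvCall
from .genome import Chromosome, GenomeSpec, Interval
from .qpcr import QpcrAssay
from .regions import Cnvr
from .simulate import BinTrack, ChromBins, PlantedCnv, TruthSet


class FormatError(ValueError):
    """Malformed input line; message carries path and line number."""


def _open(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _fail(path, lineno: int, msg: str) -> None:
    raise FormatError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------- bin tracks

def write_bintrack(track: BinTrack, path) -> None:
    with _open(path, "wt") as fh:
        fh.write(f"#bintrack\tsample={track.sample_id}\tbin_size={track.bin_size}\n")
        fh.write("chrom\tbin_start\tcount\tgc\tq0\n")
        for chrom, bins in track.chroms.items():
            starts = np.arange(len(bins.counts)) * track.bin_size
            for s, c, g, q in zip(starts, bins.counts, bins.gc, bins.q0):
                fh.write(f"{chrom}\t{s}\t{int(c)}\t{float(g)!r}\t{float(q)!r}\n")


def read_bintrack(path) -> BinTrack:
    with _open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#bintrack"):
            _fail(path, 1, "not a bintrack file (missing #bintrack header)")
        meta = dict(part.split("=", 1) for part in header.split("\t")[1:])
        bin_size = int(meta["bin_size"])
        track = BinTrack(sample_id=meta["sample"], bin_size=bin_size)
        cols = fh.readline().rstrip("\n").split("\t")
        if cols != ["chrom", "bin_start", "count", "gc", "q0"]:
            _fail(path, 2, f"unexpected columns {cols}")
        data: dict[str, list[tuple[int, int, float, float]]] = {}
        for lineno, line in enumerate(fh, start=3):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                _fail(path, lineno, f"expected 5 fields, got {len(parts)}")
            try:
                data.setdefault(parts[0], []).append(
                    (int(parts[1]), int(parts[2]), float(parts[3]), float(parts[4])))
            except ValueError as exc:
                _fail(path, lineno, str(exc))
    for chrom, rows in data.items():
        rows.sort()
        starts = [r[0] for r in rows]
        if starts != [i * bin_size for i in range(len(rows))]:
            raise FormatError(f"{path}: {chrom}: bins do not tile the chromosome")
        track.chroms[chrom] = ChromBins(
            counts=np.array([r[1] for r in rows], dtype=np.int64),
            gc=np.array([r[2] for r in rows]),
            q0=np.array([r[3] for r in rows]),
        )
    return track


# --------------------------------------------------------------- truth sets

def write_truth(truth: TruthSet, path) -> None:
    """Truth as BED6-like TSV with genome and cohort metadata in headers."""
    g = truth.genome
    with _open(path, "wt") as fh:
        fh.write(f"#truth\tseed={truth.seed}\tbin_size={g.bin_size}\n")
        for c in g.chromosomes:
            fh.write(f"#chromosome\t{c.name}\t{c.length}\t{c.baseline_cn}\n")
        for iv in g.gaps:
            fh.write(f"#gap\t{iv.chrom}\t{iv.start}\t{iv.end}\n")
        for iv in g.noisy_regions:
            fh.write(f"#noisy\t{iv.chrom}\t{iv.start}\t{iv.end}\n")
        for sid, group in truth.samples:
            fh.write(f"#sample\t{sid}\t{group}\n")
        ids = truth.sample_ids
        fh.write("chrom\tstart\tend\tlabel\tname\t" +
                 "\t".join(f"cn_{s}" for s in ids) + "\n")
        for i, ev in enumerate(truth.events):
            baseline = g.baseline_cn(ev.chrom)
            cns = [ev.cn_by_sample.get(s, baseline) for s in ids]
            fh.write(f"{ev.chrom}\t{ev.start}\t{ev.end}\t{ev.label}\tcnv_{i:04d}\t"
                     + "\t".join(str(c) for c in cns) + "\n")


def read_truth(path) -> TruthSet:
    chromosomes: list[Chromosome] = []
    gaps: list[Interval] = []
    noisy: list[Interval] = []
    samples: list[tuple[str, str]] = []
    seed = 0
    bin_size = 200
    events: list[PlantedCnv] = []
    ids: list[str] = []
    genome: GenomeSpec | None = None
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#truth"):
                meta = dict(p.split("=", 1) for p in line.split("\t")[1:])
                seed = int(meta.get("seed", 0))
                bin_size = int(meta.get("bin_size", 200))
            elif line.startswith("#chromosome\t"):
                _, name, length, baseline = line.split("\t")
                chromosomes.append(Chromosome(name, int(length), int(baseline)))
            elif line.startswith("#gap\t"):
                _, c, s, e = line.split("\t")
                gaps.append(Interval(c, int(s), int(e)))
            elif line.startswith("#noisy\t"):
                _, c, s, e = line.split("\t")
                noisy.append(Interval(c, int(s), int(e)))
            elif line.startswith("#sample\t"):
                _, sid, group = line.split("\t")
                samples.append((sid, group))
            elif line.startswith("chrom\t"):
                ids = [col[3:] for col in line.split("\t")[5:]]
                genome = GenomeSpec(chromosomes, bin_size=bin_size,
                                    gaps=gaps, noisy_regions=noisy)
            else:
                if genome is None:
                    _fail(path, lineno, "data row before column header")
                parts = line.split("\t")
                if len(parts) != 5 + len(ids):
                    _fail(path, lineno, f"expected {5 + len(ids)} fields, got {len(parts)}")
                chrom, start, end, label = parts[0], int(parts[1]), int(parts[2]), parts[3]
                baseline = genome.baseline_cn(chrom)
                cn_by_sample = {
                    s: int(v) for s, v in zip(ids, parts[5:]) if int(v) != baseline
                }
                events.append(PlantedCnv(chrom, start, end, cn_by_sample, label))
    if genome is None:
        genome = GenomeSpec(chromosomes, bin_size=bin_size,
                            gaps=gaps, noisy_regions=noisy)
    return TruthSet(genome=genome, samples=samples, events=events, seed=seed)


# -------------------------------------------------------------------- calls

_CALL_COLUMNS = ["chrom", "start", "end", "type", "sample",
                 "normalized_rd", "estimated_cn", "p_value", "q0"]


def write_calls(calls: Iterable[CnvCall], path) -> None:
    with _open(path, "wt") as fh:
        fh.write("#" + "\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.type}\t{c.sample_id}\t"
                     f"{float(c.normalized_rd)!r}\t{c.estimated_cn}\t{float(c.p_value)!r}\t{float(c.q0)!r}\n")


def read_calls(path, dialect: str = "bed_like",
               sample_id: str | None = None) -> list[CnvCall]:
    """Read calls; ``dialect`` is "bed_like" (this package's 0-based TSV)
    or "caller_text" (``type chrom:start-end length RD p q0`` lines with
    1-based inclusive coordinates, converted on input; ``sample_id``
    names the sample the file belongs to)."""
    if dialect not in ("bed_like", "caller_text"):
        raise ValueError(f"unknown dialect {dialect!r}")
    calls: list[CnvCall] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect == "bed_like":
                    if len(parts) != 9:
                        _fail(path, lineno, f"expected 9 fields, got {len(parts)}")
                    chrom, start, end, ctype, sid = parts[:5]
                    start, end = int(start), int(end)
                    rd, cn, p, q0 = (float(parts[5]), int(parts[6]),
                                     float(parts[7]), float(parts[8]))
                else:
                    if len(parts) != 6:
                        _fail(path, lineno, f"expected 6 fields, got {len(parts)}")
                    ctype, locus, length, rd_s, p_s, q0_s = parts
                    chrom, span = locus.split(":")
                    s1, e1 = span.split("-")
                    start, end = int(s1) - 1, int(e1)  # 1-based inclusive -> half-open
                    if start < 0:
                        _fail(path, lineno, "coordinate underflow after conversion")
                    if end - start != int(length):
                        _fail(path, lineno,
                              f"length {length} does not match span {end - start}")
                    rd, p, q0 = float(rd_s), float(p_s), float(q0_s)
                    cn = max(0, int(np.floor(2 * rd + 0.5)))
                    sid = sample_id or "unknown"
                if ctype not in (DELETION, DUPLICATION):
                    _fail(path, lineno, f"unknown type token {ctype!r}")
                calls.append(CnvCall(sample_id=sid, chrom=chrom, start=start,
                                     end=end, type=ctype, normalized_rd=rd,
                                     estimated_cn=cn, p_value=p, q0=q0))
            except FormatError:
                raise
            except (ValueError, IndexError) as exc:
                _fail(path, lineno, str(exc))
    return calls


# -------------------------------------------------------------------- CNVRs

def write_cnvrs(cnvrs: Iterable[Cnvr], path) -> None:
    with _open(path, "wt") as fh:
        fh.write("#chrom\tstart\tend\tcategory\tgroups\tn_samples\tsamples\n")
        for c in cnvrs:
            groups = ",".join(sorted(c.groups)) or "."
            samples = ",".join(sorted(c.samples)) or "."
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.category}\t{groups}\t"
                     f"{len(c.samples)}\t{samples}\n")


def read_cnvrs(path) -> list[Cnvr]:
    out: list[Cnvr] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                _fail(path, lineno, f"expected 7 fields, got {len(parts)}")
            chrom, start, end, category, groups, _n, samples = parts
            try:
                out.append(Cnvr(
                    chrom=chrom, start=int(start), end=int(end), category=category,
                    groups=frozenset() if groups == "." else frozenset(groups.split(",")),
                    samples=frozenset() if samples == "." else frozenset(samples.split(",")),
                ))
            except ValueError as exc:
                _fail(path, lineno, str(exc))
    return out


# ---------------------------------------------------------------------- BED

@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    rest: tuple[str, ...] = ()


def read_bed(path) -> list[BedRecord]:
    """BED 3+; header/comment/track/browser lines are skipped; extra
    columns are preserved as opaque payload."""
    out: list[BedRecord] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (not line or line.startswith("#")
                    or line.startswith("track") or line.startswith("browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                _fail(path, lineno, f"BED needs >= 3 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                _fail(path, lineno, str(exc))
            if start >= end:
                _fail(path, lineno, f"start {start} >= end {end}")
            if start < 0:
                _fail(path, lineno, f"negative start {start}")
            out.append(BedRecord(parts[0], start, end, tuple(parts[3:])))
    return out


def write_bed(records: Iterable, path) -> None:
    with _open(path, "wt") as fh:
        for r in records:
            rest = "\t".join(getattr(r, "rest", ()))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}" + (f"\t{rest}" if rest else "") + "\n")


def bed_to_intervals(records: Iterable[BedRecord]) -> list[Interval]:
    return [Interval(r.chrom, r.start, r.end) for r in records]


# -------------------------------------------------------------- annotations

def read_annotations(path, kind: str, dialect: str) -> list[AnnotationRecord]:
    """Gene/QTL table: chrom, start, end, id[, name[, attribute[, strand]]].

    ``dialect`` must be declared: "bed" (0-based half-open) or
    "one_based" (1-based inclusive; converted on input).  No
    auto-detection — a silent off-by-one is the classic failure mode.
    """
    if dialect not in ("bed", "one_based"):
        raise ValueError(f"unknown coordinate dialect {dialect!r}")
    out: list[AnnotationRecord] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                _fail(path, lineno, f"need >= 4 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                _fail(path, lineno, str(exc))
            if dialect == "one_based":
                start -= 1
                if start < 0:
                    _fail(path, lineno, "coordinate underflow after conversion")
            if start >= end:
                _fail(path, lineno, f"start {start} >= end {end}")
            out.append(AnnotationRecord(
                chrom=parts[0], start=start, end=end, id=parts[3],
                name=parts[4] if len(parts) > 4 else "",
                kind=kind,
                attribute=parts[5] if len(parts) > 5 else "",
                strand=parts[6] if len(parts) > 6 else ".",
            ))
    ids = [a.id for a in out]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate feature ids")
    return out


def write_overlaps(pairs: Iterable[tuple], path) -> None:
    """Overlap report: CNVR coordinates, feature id/name/kind/attribute, bp."""
    with _open(path, "wt") as fh:
        fh.write("#cnvr_chrom\tcnvr_start\tcnvr_end\tcnvr_category\t"
                 "feature_id\tfeature_name\tkind\tattribute\toverlap_bp\n")
        for cnvr, feat, ov in pairs:
            fh.write(f"{cnvr.chrom}\t{cnvr.start}\t{cnvr.end}\t{cnvr.category}\t"
                     f"{feat.id}\t{feat.name}\t{feat.kind}\t{feat.attribute}\t{ov}\n")


# --------------------------------------------------------------------- qPCR

def read_qpcr_csv(path, predictions: Mapping | None = None) -> list[QpcrAssay]:
    """Ct measurements CSV with columns region_id, sample_id, role
    (test|reference), assay (target|control), replicate, ct.

    The reference rows of a region anchor the two-copy scale for every
    test sample of that region.  ``predictions`` maps (region_id,
    sample_id) — or region_id alone — to the pipeline's
    gain/loss/normal class.
    """
    df = pd.read_csv(path)
    required = {"region_id", "sample_id", "role", "assay", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad_roles = set(df["role"]) - {"test", "reference"}
    if bad_roles:
        raise FormatError(f"{path}: unknown roles {sorted(bad_roles)}")
    bad_assays = set(df["assay"]) - {"target", "control"}
    if bad_assays:
        raise FormatError(f"{path}: unknown assays {sorted(bad_assays)}")

    def reps(sub: pd.DataFrame, assay: str) -> tuple[float, ...]:
        vals = sub.loc[sub["assay"] == assay].sort_values("replicate")["ct"]
        return tuple(float(v) for v in vals)

    out: list[QpcrAssay] = []
    for region, region_df in df.groupby("region_id", sort=True):
        ref = region_df[region_df["role"] == "reference"]
        ref_target, ref_control = reps(ref, "target"), reps(ref, "control")
        if not ref_target or not ref_control:
            raise FormatError(f"{path}: region {region}: missing reference sample")
        tests = region_df[region_df["role"] == "test"]
        for sample, sub in tests.groupby("sample_id", sort=True):
            predicted = None
            if predictions is not None:
                predicted = predictions.get((region, sample), predictions.get(region))
            out.append(QpcrAssay(
                region_id=str(region), sample_id=str(sample),
                ct_target=reps(sub, "target"), ct_control=reps(sub, "control"),
                reference_ct_target=ref_target, reference_ct_control=ref_control,
                predicted_class=predicted,
            ))
    return out
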