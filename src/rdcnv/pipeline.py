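"""End-to-end orchestration: tracks (or calls) in, differential CNVRs out.

Stages mirror the analysis as a whole: per-sample calling and QC,
within-group common-CNVR construction, shared/group-specific splitting,
differential-CNVR merging, optional gene/QTL annotation, and summary
statistics.  Every artifact is a plain TSV under the output directory
plus a machine-readable ``manifest.json`` carrying the configuration,
its hash, and per-stage counts.  Given fixed seeds the run is
deterministic — two runs write byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import io as rdio
from .annotate import AnnotationRecord, overlap_features, summarize_gene_coverage
from .caller import CnvCall
from .config import PipelineConfig
from .genome import Interval
from .regions import (differential_cnvrs, group_common_cnvrs,
                      split_shared_specific)
from .simulate import BinTrack, TruthSet
from .summarize import (category_counts, length_stats, per_sample_counts,
                        recovery_metrics, size_histogram)

logger = logging.getLogger("rdcnv")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    *,
    tracks: Mapping[str, BinTrack] | None = None,
    calls_by_sample: Mapping[str, Sequence[CnvCall]] | None = None,
    groups: Mapping[str, str],
    gaps: Iterable[Interval] = (),
    baseline_cn_by_chrom: Mapping[str, int] | None = None,
    genes: Sequence[AnnotationRecord] = (),
    qtls: Sequence[AnnotationRecord] = (),
    truth: TruthSet | None = None,
) -> dict:
    """Run calling through summaries; returns the manifest dict.

    Provide either ``tracks`` (binned coverage per sample; calling and
    QC run here) or ``calls_by_sample`` (pre-made, already conforming
    calls; QC still applies).  ``groups`` maps each sample to "high" or
    "low".
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gaps = list(gaps)
    counts: dict[str, int] = {}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("calling")
        from .caller import call_cnvs, gc_correct, qc_filter, segment

        if calls_by_sample is None:
            if tracks is None:
                raise ValueError("need tracks or calls_by_sample")
            raw: dict[str, list[CnvCall]] = {}
            for sample in sorted(tracks):
                profile = gc_correct(tracks[sample], baseline_cn_by_chrom)
                segs = segment(profile, config.del_enter, config.dup_enter,
                               config.max_bridge, config.smooth_window,
                               config.del_confirm, config.dup_confirm)
                raw[sample] = call_cnvs(profile, segs)
        else:
            raw = {s: list(c) for s, c in sorted(calls_by_sample.items())}
        counts["raw_calls"] = sum(len(v) for v in raw.values())
        filtered = {
            sample: qc_filter(calls, gaps, config.min_size, config.max_p,
                              config.max_q0, set(config.drop_chroms))
            for sample, calls in raw.items()
        }
        all_calls = [c for s in sorted(filtered) for c in filtered[s]]
        counts["filtered_calls"] = len(all_calls)
        rdio.write_calls(all_calls, out / "calls.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("calling", exc) from exc

    try:
        stage("common CNVRs per group")
        by_group: dict[str, dict[str, list[CnvCall]]] = {"high": {}, "low": {}}
        for sample, calls in filtered.items():
            if sample not in groups:
                raise ValueError(f"sample {sample!r} has no group assignment")
            by_group[groups[sample]][sample] = calls
        common = {}
        for group in ("high", "low"):
            common[group] = group_common_cnvrs(
                by_group[group], config.reciprocal_threshold, group,
                config.merge_overlap_bp, config.require_same_type)
            counts[f"common_cnvrs_{group}"] = len(common[group])
            rdio.write_cnvrs(common[group], out / f"common_{group}.tsv")
    except Exception as exc:
        raise PipelineError("common CNVRs", exc) from exc

    try:
        stage("shared vs group-specific")
        shared, high_spec, low_spec = split_shared_specific(
            common["high"], common["low"], config.shared_criterion,
            config.reciprocal_threshold, config.merge_overlap_bp)
        counts["shared_cnvrs"] = len(shared)
        counts["high_specific"] = len(high_spec)
        counts["low_specific"] = len(low_spec)
        rdio.write_cnvrs(shared, out / "shared.tsv")
        rdio.write_cnvrs(high_spec, out / "high_specific.tsv")
        rdio.write_cnvrs(low_spec, out / "low_specific.tsv")

        stage("differential CNVRs")
        differential = differential_cnvrs(high_spec, low_spec, config.merge_overlap_bp)
        counts["differential_cnvrs"] = len(differential)
        rdio.write_cnvrs(differential, out / "differential.tsv")
    except Exception as exc:
        raise PipelineError("CNVR algebra", exc) from exc

    try:
        stage("annotation")
        if genes:
            pairs = overlap_features(differential, genes)
            rdio.write_overlaps(pairs, out / "overlaps_genes.tsv")
            counts["gene_overlap_pairs"] = len(pairs)
        if qtls:
            pairs = overlap_features(differential, qtls)
            rdio.write_overlaps(pairs, out / "overlaps_qtls.tsv")
            counts["qtl_overlap_pairs"] = len(pairs)
    except Exception as exc:
        raise PipelineError("annotation", exc) from exc

    try:
        stage("summaries")
        report: list[str] = []
        psc = per_sample_counts(all_calls)
        psc.to_csv(out / "per_sample_counts.tsv", sep="\t")
        for sample, row in psc.iterrows():
            report.append(f"calls.{sample}.duplication\t{row['n_duplication']}")
            report.append(f"calls.{sample}.deletion\t{row['n_deletion']}")
        if differential:
            ls = length_stats(differential)
            report += [
                f"differential.n\t{ls.n}",
                f"differential.mean_kb\t{ls.mean_kb:.2f}",
                f"differential.median_kb\t{ls.median_kb:.2f}",
                f"differential.min_kb\t{ls.min_kb:.2f}",
                f"differential.max_kb\t{ls.max_kb:.2f}",
                f"differential.std_kb\t{ls.std_kb:.2f}",
                f"differential.total_mb\t{ls.total_mb:.2f}",
            ]
            cc = category_counts(differential)
            report += [
                f"differential.deletion.n\t{cc.n_deletion}",
                f"differential.duplication.n\t{cc.n_duplication}",
                f"differential.both.n\t{cc.n_both}",
                f"differential.deletion.mb\t{cc.deletion_mb:.2f}",
                f"differential.duplication.mb\t{cc.duplication_mb:.2f}",
                f"differential.both.mb\t{cc.both_mb:.2f}",
            ]
            for label, frac in size_histogram(differential).items():
                report.append(f"differential.size.{label}\t{frac:.4f}")
        if genes:
            n_hit, frac, n_genes = summarize_gene_coverage(differential, genes)
            report += [
                f"genes.cnvrs_with_gene\t{n_hit}",
                f"genes.fraction_with_gene\t{frac:.4f}",
                f"genes.distinct\t{n_genes}",
            ]
        if truth is not None:
            rm = recovery_metrics(all_calls, truth)
            report += [
                f"recovery.sensitivity\t{rm.sensitivity:.4f}",
                f"recovery.fdr\t{rm.fdr:.4f}",
                f"recovery.cn_exact_fraction\t{rm.cn_exact_fraction:.4f}",
            ]
            counts["truth_units"] = rm.n_truth_units
        (out / "summary.tsv").write_text("\n".join(report) + "\n")
    except Exception as exc:
        raise PipelineError("summaries", exc) from exc

    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "counts": counts,
        "groups": dict(sorted(groups.items())),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline done: %s", counts)
    return manifest
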