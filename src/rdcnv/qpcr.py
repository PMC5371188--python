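"""qPCR copy-number estimation by the 2^-ddCt method and validation rates.

The relative quantification model: each PCR cycle doubles the template,
so a cycle-threshold (Ct) difference of one cycle is a two-fold template
difference.  With a single-copy-per-haploid control locus assumed to be
present at two copies, the estimated copy number of a test region is

    2 * 2 ** (-ddCt),
    ddCt = (Ct_target - Ct_control)_test - (Ct_target - Ct_control)_reference

where the reference sample is known (from sequencing) to carry two
copies.  An estimate at or above ~3 is scored a gain, at or below ~1 a
loss.  Primer efficiency is checked from a standard curve of Ct versus
log10 template amount: a slope of -3.32 cycles/decade is a perfectly
doubling (100% efficient) reaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Mapping, Sequence

import numpy as np

GAIN = "gain"
LOSS = "loss"
NORMAL = "normal"


@dataclass(frozen=True)
class QpcrAssay:
    """Replicate Ct values for one test region in one sample.

    ``ct_target``/``ct_control`` are the test sample's replicates for
    the assayed region and the two-copy control locus;
    ``reference_ct_*`` are the same for the two-copy reference sample.
    ``predicted_class`` is the sequencing pipeline's gain/loss/normal
    prediction, used for concordance.
    """

    region_id: str
    sample_id: str
    ct_target: tuple[float, ...]
    ct_control: tuple[float, ...]
    reference_ct_target: tuple[float, ...]
    reference_ct_control: tuple[float, ...]
    predicted_class: str | None = None

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_control"):
            reps = getattr(self, name)
            object.__setattr__(self, name, tuple(float(x) for x in reps))
            if not reps:
                raise ValueError(f"{name}: need at least one replicate")
            if any(x <= 0 for x in reps):
                raise ValueError(f"{name}: Ct values must be positive")
        for name in ("reference_ct_target", "reference_ct_control"):
            reps = getattr(self, name)
            object.__setattr__(self, name, tuple(float(x) for x in reps))
            if any(x <= 0 for x in reps):
                raise ValueError(f"{name}: Ct values must be positive")
        if self.predicted_class not in (None, GAIN, LOSS, NORMAL):
            raise ValueError(f"unknown predicted class {self.predicted_class!r}")


def relative_cn(assay: QpcrAssay) -> float:
    """Estimated copies of the test region: 2 * 2^-ddCt.

    Replicates are averaged arithmetically; the reference sample must be
    present (it anchors the two-copy scale).
    """
    if not assay.reference_ct_target or not assay.reference_ct_control:
        raise ValueError(f"assay {assay.region_id}/{assay.sample_id}: missing reference sample")
    dct_test = fmean(assay.ct_target) - fmean(assay.ct_control)
    dct_ref = fmean(assay.reference_ct_target) - fmean(assay.reference_ct_control)
    ddct = dct_test - dct_ref
    return 2.0 * 2.0 ** (-ddct)


def classify_cn(copies: float, gain_threshold: float = 3.0,
                loss_threshold: float = 1.0) -> str:
    """Gain at >= gain_threshold copies, loss at <= loss_threshold, else normal."""
    if loss_threshold >= gain_threshold:
        raise ValueError("loss_threshold must be below gain_threshold")
    if copies < 0:
        raise ValueError("copies must be >= 0")
    if copies >= gain_threshold:
        return GAIN
    if copies <= loss_threshold:
        return LOSS
    return NORMAL


def std_curve_efficiency(dilution_log10: Sequence[float],
                         ct: Sequence[float]) -> tuple[float, float]:
    """Least-squares standard curve: (slope, amplification efficiency).

    ``dilution_log10`` is log10 of the template amount for each point.
    Efficiency = 10^(-1/slope) - 1, so a slope of -log2(10)^-1 decades
    per cycle, i.e. -3.3219 cycles per decade, is efficiency 1 (exact
    doubling per cycle).
    """
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(ct, dtype=float)
    if len(x) != len(y):
        raise ValueError("dilution and Ct lists differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 standard-curve points")
    if len(set(x.tolist())) < 2:
        raise ValueError("standard curve needs distinct dilutions")
    slope, _ = np.polyfit(x, y, 1)
    if slope == 0:
        raise ValueError("flat standard curve: efficiency undefined")
    return float(slope), float(10.0 ** (-1.0 / slope) - 1.0)


def validation_rate(
    assays: Iterable[QpcrAssay] | Mapping[str, Sequence[QpcrAssay]],
    gain_threshold: float = 3.0,
    loss_threshold: float = 1.0,
) -> tuple[dict[str, float], float]:
    """Per-sample percent of assays whose qPCR class matches the
    pipeline's prediction, and the unweighted cohort mean.

    Accepts a flat iterable of assays (grouped by sample id) or a
    mapping sample -> assays.  Samples with zero assays are excluded
    with a warning.  A predicted-normal region confirmed normal counts
    as concordant.
    """
    if isinstance(assays, Mapping):
        grouped: dict[str, list[QpcrAssay]] = {k: list(v) for k, v in assays.items()}
    else:
        grouped = {}
        for a in assays:
            grouped.setdefault(a.sample_id, []).append(a)

    per_sample: dict[str, float] = {}
    for sample, items in grouped.items():
        if not items:
            warnings.warn(f"sample {sample!r} has no assays; excluded", stacklevel=2)
            continue
        hits = 0
        for a in items:
            if a.predicted_class is None:
                raise ValueError(
                    f"assay {a.region_id}/{a.sample_id} has no pipeline prediction")
            observed = classify_cn(relative_cn(a), gain_threshold, loss_threshold)
            hits += observed == a.predicted_class
        per_sample[sample] = 100.0 * hits / len(items)
    if not per_sample:
        raise ValueError("no samples with assays")
    return per_sample, fmean(per_sample.values())
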