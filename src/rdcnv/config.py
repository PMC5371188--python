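"""Pipeline configuration: every tunable threshold in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class PipelineConfig:
    """All thresholds of the discovery pipeline with their defaults.

    Unknown keys are rejected on load; ranges are validated so that a
    typo'd config fails loudly rather than silently calling nothing.
    """

    # binning / caller
    bin_size: int = 200
    del_enter: float = 0.75
    dup_enter: float = 1.25
    max_bridge: int = 5
    smooth_window: int = 7
    del_confirm: float | None = 0.65
    dup_confirm: float | None = 1.35
    # QC filters
    max_p: float = 0.01
    min_size: int = 1_000
    max_q0: float = 0.5
    drop_chroms: tuple[str, ...] = ("chrUn",)
    # CNVR algebra
    reciprocal_threshold: float = 0.3
    merge_overlap_bp: int = 1
    shared_criterion: str = "reciprocal"  # or "overlap"
    require_same_type: bool = True
    # qPCR classification
    gain_threshold: float = 3.0
    loss_threshold: float = 1.0
    # simulation / reproducibility
    seed: int = 1
    lambda_per_bin: float = 20.0
    gc_bias_amplitude: float = 0.3
    q0_background: float = 0.05
    q0_elevated: float = 0.8
    # input coordinate dialects (never inferred)
    calls_dialect: str = "bed_like"
    genes_dialect: str = "bed"
    qtls_dialect: str = "bed"

    def __post_init__(self) -> None:
        self.drop_chroms = tuple(self.drop_chroms)
        if self.bin_size <= 0 or self.min_size < 0 or self.merge_overlap_bp < 1:
            raise ValueError("bin_size > 0, min_size >= 0, merge_overlap_bp >= 1 required")
        if not (0 < self.del_enter < 1 < self.dup_enter):
            raise ValueError("need 0 < del_enter < 1 < dup_enter")
        if not (0 < self.max_p <= 1) or not (0 <= self.max_q0 <= 1):
            raise ValueError("max_p in (0,1], max_q0 in [0,1] required")
        if not (0 <= self.reciprocal_threshold < 1):
            raise ValueError("reciprocal_threshold must be in [0,1)")
        if self.shared_criterion not in ("reciprocal", "overlap"):
            raise ValueError(f"unknown shared_criterion {self.shared_criterion!r}")
        if self.loss_threshold >= self.gain_threshold:
            raise ValueError("loss_threshold must be below gain_threshold")
        if self.max_bridge < 0 or self.smooth_window < 1:
            raise ValueError("max_bridge >= 0 and smooth_window >= 1 required")
        if self.del_confirm is not None and not 0 <= self.del_confirm < 1:
            raise ValueError("del_confirm must be in [0, 1)")
        if self.dup_confirm is not None and self.dup_confirm <= 1:
            raise ValueError("dup_confirm must be > 1")
        if self.lambda_per_bin <= 0:
            raise ValueError("lambda_per_bin must be > 0")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        for name in ("calls_dialect", "genes_dialect", "qtls_dialect"):
            val = getattr(self, name)
            allowed = ("bed_like", "caller_text") if name == "calls_dialect" \
                else ("bed", "one_based")
            if val not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {val!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drop_chroms"] = list(d["drop_chroms"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
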