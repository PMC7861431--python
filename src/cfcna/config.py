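"""Pipeline configuration: every numeric threshold in one serializable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Defaults are the published shallow-WGS cfDNA settings: 500 kb bins,
    |Z| >= 4.95 with >= 1.5% effect size for whole-genome calls, targeted z
    cuts 3.0/5.0, 2.5% MAE panel QC, amplification ratio 1.5 (fallback
    effect size 4.5%), CIN at >= 10 chromosomes, chromosomes 19/X/Y
    excluded."""

    bin_width: int = 500_000
    z_min: float = 4.95
    es_min: float = 0.015
    targeted_z_low: float = 3.0
    targeted_z_high: float = 5.0
    mae_threshold: float = 0.025
    amp_ratio: float = 1.5
    fallback_es: float = 0.045
    cin_min_chromosomes: int = 10
    excluded_chromosomes: list[str] = field(
        default_factory=lambda: ["19", "X", "Y"])
    n_ref: int = 100
    min_ref: int = 25
    panel_path: str | None = None
    blacklist_bed: str | None = None
    regions_bed: str | None = None
    genes_bed: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bin_width", "z_min", "es_min", "targeted_z_low",
                     "targeted_z_high", "mae_threshold", "amp_ratio",
                     "fallback_es", "cin_min_chromosomes", "n_ref", "min_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
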