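"""Pipeline configuration: one record, loadable from YAML, written back
beside every run's outputs for provenance."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Tunable parameters of the case pipeline.

    ``isodose_threshold_gy`` defaults to 56 Gy — the threshold at which
    resection margins relate to recurrence risk. ``hu_threshold`` is the CT
    bone-segmentation cutoff; ``cortical_shell_mm`` the assumed cortical
    plate thickness used when classifying osteotomy planes.
    """

    hu_threshold: float = 300.0
    isodose_threshold_gy: float = 56.0
    cortical_shell_mm: float = 2.0
    normality_alpha: float = 0.05
    resample_spacing_mm: float | None = None  # None: keep the CT grid
    seed: int = 0

    def __post_init__(self) -> None:
        if self.isodose_threshold_gy <= 0:
            raise ValueError("isodose threshold must be positive")
        if not (0.0 < self.normality_alpha < 1.0):
            raise ValueError("normality alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
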