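"""Run configuration shared by the CLI commands.

Defaults encode the analysis protocol: 2.5 s windows at 50 Hz, a 3-level
packet decomposition (8 sub-bands), the eleven candidate mother wavelets,
and 10-fold stratified cross-validation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .wavelets import CANDIDATE_WAVELETS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    window_seconds: float = 2.5
    target_rate: float = 50.0
    level: int = 3
    candidates: list[str] = field(default_factory=lambda: list(CANDIDATE_WAVELETS))
    classifiers: list[str] = field(default_factory=lambda: ["dt", "svm"])
    k: int = 10
    seed: int = 0
    pooling: str = "pooled"          # "pooled" | "per_node" entropy pooling
    axis_mode: str = "mean"          # "mean" | "magnitude"
    label_policy: str = "pure"       # "pure" | "majority"
    overlap: float = 0.0
    units: str = "m_per_s2"          # "m_per_s2" | "g"
    n_segments_per_class: int = 120  # synthetic benchmark size
    data_dir: str | None = None
    out_dir: str = "wavehar_out"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def merged(self, **overrides) -> "RunConfig":
        """Copy with non-None overrides applied (flags beat config file)."""
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)
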