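"""Pipeline configuration: every tunable with its published default.

Defaults mirror the acquisition and analysis settings the framework was
built around: up to 44 cells per trajectory, a 65-degree cone half-angle,
70% protein completeness, 20 spatial bins, |beta1| > 1 & Q < 0.05 for strong
zonation, |Delta_beta1| > 1 & Q < 0.05 for zonation loss, and 60 variable
DIA windows over 380-980 m/z.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # cell selection
    k: int = 44
    cone_half_angle: float = 65.0
    mode: str = "auto"  # "auto" | "manual"
    anchor_a: tuple[float, float] | None = None  # manual central anchor
    anchor_b: tuple[float, float] | None = None  # manual portal anchor
    orientation: str = "central_zero"
    min_vein_area: float = 900.0
    blur_sigma: float = 5.0
    dilation_radius: int = 10
    annulus_width: int = 20
    # QC + gradient analysis
    min_completeness: float = 0.70
    tukey_k: float = 1.5
    n_bins: int = 20
    q_threshold: float = 0.05
    strong_beta: float = 1.0
    delta_threshold: float = 1.0
    # DIA window design
    n_windows: int = 60
    mz_low: float = 380.0
    mz_high: float = 980.0
    min_window_width: float = 0.0
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if not 0 < self.cone_half_angle <= 90:
            raise ValueError("cone_half_angle must be in (0, 90]")
        if self.mode not in ("auto", "manual"):
            raise ValueError("mode must be 'auto' or 'manual'")
        if self.mode == "manual" and (self.anchor_a is None or self.anchor_b is None):
            raise ValueError("manual mode needs anchor_a and anchor_b")
        if not 0 < self.min_completeness <= 1:
            raise ValueError("min_completeness must be in (0, 1]")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        if self.n_windows < 1 or self.mz_high <= self.mz_low:
            raise ValueError("invalid DIA window settings")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("anchor_a", "anchor_b"):
            if data.get(key) is not None:
                data[key] = tuple(float(v) for v in data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
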