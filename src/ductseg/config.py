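"""Pipeline configuration: every tunable with its default, YAML-loadable.

Defaults follow the operating point of the full-scale pipeline: 128 px
patches, 20 px inference stride, 25 px local-mean windows for both duct
binarisation and boundary suppression, 1500 px region-merge threshold,
0.9 circularity / 0.5 mean-area outlier rule, 2400 dpi scans.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    patch_size: int = 128
    stride: int = 20
    duct_window: int = 25
    duct_offset: float = 0.05
    ring_window: int = 25
    merge_min_area: int = 1500
    circularity_threshold: float = 0.9
    area_fraction: float = 0.5
    dpi: float = 2400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size <= 0 or self.stride <= 0 or self.stride > self.patch_size:
            raise ValueError("need 0 < stride <= patch_size")
        for name in ("duct_window", "ring_window"):
            v = getattr(self, name)
            if v <= 0 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and positive")
        if not (0.0 <= self.duct_offset < 1.0):
            raise ValueError("duct_offset must be in [0, 1)")
        if self.merge_min_area < 1:
            raise ValueError("merge_min_area must be positive")
        if not (0.0 < self.area_fraction <= 1.0):
            raise ValueError("area_fraction must be in (0, 1]")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config file, rejecting unknown keys."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
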