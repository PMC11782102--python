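"""Run configuration shared by the pipeline and the CLI.

Defaults reproduce the measurement parameters the method was designed
with: 0.5 mm resampling, 10 mm tangent lookahead, a +/-2-point
moving-average window, and the 90th-percentile summary.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .dp_ratio import PARENCHYMA_EXCLUDES_DUCT, WHOLE_PANCREAS

__all__ = ["RunConfig"]


@dataclasses.dataclass
class RunConfig:
    resample_step_mm: float = 0.5
    tangent_lookahead_mm: float = 10.0
    smoothing_half_width: int = 2
    section_half_extent_mm: float = 40.0
    in_plane_step_mm: float = 0.5
    percentile_level: float = 90.0
    denominator_convention: str = PARENCHYMA_EXCLUDES_DUCT
    dijkstra_exponent: float = 2.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for field in ("resample_step_mm", "tangent_lookahead_mm",
                      "section_half_extent_mm", "in_plane_step_mm"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        if not (0 < self.percentile_level <= 100):
            raise ValueError("percentile_level must be in (0, 100]")
        if self.denominator_convention not in (PARENCHYMA_EXCLUDES_DUCT,
                                               WHOLE_PANCREAS):
            raise ValueError(
                f"unknown denominator_convention: {self.denominator_convention}")
        if self.smoothing_half_width < 0:
            raise ValueError("smoothing_half_width must be nonnegative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        data = {**(data or {}), **overrides}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
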