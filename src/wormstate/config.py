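"""Experiment configuration with validated, publication-default values."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .sleep import GEOMETRY_THRESHOLDS, geometry_threshold

__all__ = ["ExperimentConfig"]


@dataclass
class ExperimentConfig:
    """All tunable analysis parameters in one validated record.

    Defaults are the values used throughout the behavioral pipeline:
    3 fps imaging, a 30-grey-level pixel-change threshold (well above
    CMOS sensor noise; the RIS rig's high-dynamic-range sensor uses 400),
    20-s activity smoothing normalized to the 95th percentile, and bout
    rules of 30 s minimum with sub-15-s twitch tolerance.  The sleep
    threshold defaults to the geometry's standard value unless overridden.
    """

    geometry: str = "chamber_500um"
    fps: float = 3.0
    pixel_delta_threshold: float = 30.0
    smoothing_window_s: float = 20.0
    norm_percentile: float = 95.0
    sleep_threshold: float | None = None  # None -> geometry default
    min_bout_s: float = 30.0
    max_twitch_s: float = 15.0
    stimulus_times_s: list[float] = field(default_factory=list)
    pre_window_s: float = 10.0
    post_window_s: float = 10.0
    artifact_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        geometry_threshold(self.geometry)  # raises for unknown labels
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.pixel_delta_threshold <= 0:
            raise ValueError("pixel_delta_threshold must be > 0")
        if not (0 < self.norm_percentile <= 100):
            raise ValueError("norm_percentile must be in (0, 100]")
        if self.smoothing_window_s < 0 or self.min_bout_s <= 0 or self.max_twitch_s < 0:
            raise ValueError("invalid smoothing/bout durations")
        if self.sleep_threshold is not None and self.sleep_threshold <= 0:
            raise ValueError("sleep_threshold must be > 0")
        if self.artifact_s >= self.post_window_s:
            raise ValueError("artifact_s must be shorter than post_window_s")

    @property
    def effective_sleep_threshold(self) -> float:
        if self.sleep_threshold is not None:
            return self.sleep_threshold
        return geometry_threshold(self.geometry)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
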