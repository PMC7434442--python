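"""Pipeline configuration.

All tunable thresholds of the feature-extraction pipeline live in a single
:class:`Config` dataclass so that a run is fully described by (input data,
config, seed).  Durations are given in seconds and converted to frame counts
with the configured frame rate; fractional thresholds are relative to
trial-level reference quantities (maximum speed, maximum paw height), which
makes the segmentation invariant to the spatial calibration of the tracker.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError

_FRACTION_FIELDS = (
    "shake_threshold_frac",
    "guard_elevation_frac",
    "movement_speed_frac",
    "peak_prominence_frac",
)


@dataclass
class Config:
    """Parameters of the kinematic pipeline.

    Attributes
    ----------
    fps
        Video frame rate in frames per second (recordings analysed here are
        made at 2000 fps, i.e. 0.5 ms per frame).
    sg_order
        Polynomial order of the Savitzky-Golay smoother.
    sg_window_s
        Savitzky-Golay window duration in seconds (21 frames at 2000 fps).
    axis_window_s
        Duration of the sliding window used to estimate the moving principal
        axis of paw displacement.
    shake_threshold_frac
        Minimum inter-extremum displacement swing, as a fraction of the
        reference paw height, for a swing to count toward shaking.
    guard_elevation_frac
        Elevation tolerance (fraction of reference paw height) above the
        final resting height below which the paw counts as "at rest".
    movement_speed_frac
        Speed threshold, as a fraction of the trial's maximum speed, used to
        delimit the movement window.
    movement_speed_min
        Optional absolute speed floor (spatial units / s) added to the
        relative movement threshold; 0 disables it.  Useful when tracker
        jitter has a known magnitude.
    peak_prominence_frac
        Minimum prominence (fraction of maximum baseline-relative height)
        for a paw-height peak to qualify as the withdrawal peak t*.
    extremum_prune_frac
        Displacement swings smaller than this fraction of the displacement
        range are treated as jitter/plateaus and merged before the
        alternating-extrema scan; 0 disables pruning.
    baseline_relative_threshold
        If True (default) the shaking threshold references the
        baseline-relative maximum paw height over the movement window; if
        False, the raw maximum smoothed y.
    post_window_only
        If True (default) post-peak height/velocity maxima are computed over
        the post-peak window only, not the whole trial.
    invert_y
        If True, reflect the y series about its maximum on ingest so that
        larger y always means a higher paw (image coordinates are
        down-positive).
    seed
        Seed for all stochastic operations (bootstrap, simulation).
    """

    fps: float = 2000.0
    sg_order: int = 3
    sg_window_s: float = 0.0105
    axis_window_s: float = 0.04
    shake_threshold_frac: float = 0.35
    guard_elevation_frac: float = 0.05
    movement_speed_frac: float = 0.05
    movement_speed_min: float = 0.0
    peak_prominence_frac: float = 0.10
    extremum_prune_frac: float = 0.01
    baseline_relative_threshold: bool = True
    post_window_only: bool = True
    invert_y: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ConfigError(f"fps must be positive, got {self.fps}")
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if not 0.0 <= self.extremum_prune_frac < 1.0:
            raise ConfigError(
                f"extremum_prune_frac must lie in [0, 1), got {self.extremum_prune_frac}"
            )
        if self.movement_speed_min < 0:
            raise ConfigError("movement_speed_min must be >= 0")
        if self.sg_order < 1:
            raise ConfigError("sg_order must be >= 1")
        if self.sg_window <= self.sg_order:
            raise ConfigError(
                f"Savitzky-Golay window ({self.sg_window} frames) must exceed "
                f"the polynomial order ({self.sg_order})"
            )
        if self.axis_window < 4:
            raise ConfigError(
                f"axis window ({self.axis_window} frames) must span >= 4 frames"
            )

    @property
    def sg_window(self) -> int:
        """Savitzky-Golay window length in frames (always odd)."""
        w = int(round(self.sg_window_s * self.fps))
        if w % 2 == 0:
            w += 1
        return w

    @property
    def axis_window(self) -> int:
        """Principal-axis window length in frames."""
        return max(int(round(self.axis_window_s * self.fps)), 1)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "Config":
        """Load a config from a YAML or JSON file (by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
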