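"""Per-trial kinematic feature extraction and table standardization.

Eleven named features are computed for every trial, four on the pre-peak
window [start, t*] and seven on the post-peak window [t*, end):

pre-peak:   max_height_pre, max_x_velocity_pre, max_y_velocity_pre, distance_pre
post-peak:  max_height_post, max_x_velocity_post, max_y_velocity_post,
            distance_post, shake_count, shaking_duration_s, guarding_duration_s

Heights are baseline-relative maxima of the smoothed vertical position,
velocities are maxima of |vx| and |vy| (absolute values, so mirror-image
camera placement cannot change a feature), and distances are the arc length
of the smoothed path.  Shake/guard fields come from the displacement
segmentation.  Downstream modeling uses either the 4 pre-peak features or
the 7 post-peak features; all 11 are always computed and stored.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .config import Config
from .errors import TrialError, ZeroVarianceError
from .io import Trajectory
from .kinematics import (
    MovementWindow,
    PeakAnnotation,
    SmoothedTrajectory,
    detect_movement_window,
    find_first_peak,
    smooth,
)
from .projection import (
    AxisSeries,
    DisplacementSeries,
    ShakeSegmentation,
    moving_principal_axis,
    project_displacement,
    segment_shaking_guarding,
)

PRE_FEATURES = (
    "max_height_pre",
    "max_x_velocity_pre",
    "max_y_velocity_pre",
    "distance_pre",
)
POST_FEATURES = (
    "max_height_post",
    "max_x_velocity_post",
    "max_y_velocity_post",
    "distance_post",
    "shake_count",
    "shaking_duration_s",
    "guarding_duration_s",
)
ALL_FEATURES = PRE_FEATURES + POST_FEATURES


def feature_set(name: str) -> tuple[str, ...]:
    """Resolve a feature-set selector ('pre', 'post' or 'all')."""
    try:
        return {"pre": PRE_FEATURES, "post": POST_FEATURES, "all": ALL_FEATURES}[name]
    except KeyError:
        raise ValueError(f"unknown feature set {name!r}; use 'pre', 'post' or 'all'")


@dataclass(frozen=True)
class FeatureVector:
    max_height_pre: float
    max_x_velocity_pre: float
    max_y_velocity_pre: float
    distance_pre: float
    max_height_post: float
    max_x_velocity_post: float
    max_y_velocity_post: float
    distance_post: float
    shake_count: float
    shaking_duration_s: float
    guarding_duration_s: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class TrialAnalysis:
    """Full per-trial analysis bundle (intermediates kept for audit/plots)."""

    smoothed: SmoothedTrajectory
    window: MovementWindow
    peak: PeakAnnotation
    axes: AxisSeries
    displacement: DisplacementSeries
    segmentation: ShakeSegmentation
    features: FeatureVector


def _arc_length(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(np.hypot(np.diff(x), np.diff(y))))


def analyze_trial(traj: Trajectory, config: Config) -> TrialAnalysis:
    """Run the full kinematic pipeline on one trajectory.

    Raises a :class:`~paws.errors.TrialError` subclass when the trial has no
    detectable movement or no qualifying withdrawal peak; batch drivers
    catch these and record the trial as rejected.
    """
    sm = smooth(traj, config)
    window = detect_movement_window(sm, config)
    peak = find_first_peak(sm, window, config)
    axes = moving_principal_axis(sm, window, config)
    disp = project_displacement(sm, axes, config)
    seg = segment_shaking_guarding(disp, sm, peak, window, config)

    lo, star, hi = window.start_idx, peak.t_star_idx, window.end_idx
    base = window.baseline_y
    y, vx, vy = sm.y_s, sm.vx, sm.vy

    pre = slice(lo, star + 1)  # pre-peak window includes t*
    post = slice(star, hi)     # half-open post-peak window
    if not config.post_window_only:
        post = slice(lo, hi)

    fv = FeatureVector(
        max_height_pre=max(float(np.max(y[pre]) - base), 0.0),
        max_x_velocity_pre=float(np.max(np.abs(vx[pre]))),
        max_y_velocity_pre=float(np.max(np.abs(vy[pre]))),
        distance_pre=_arc_length(sm.x_s[lo : star + 1], y[lo : star + 1]),
        max_height_post=max(float(np.max(y[post]) - base), 0.0),
        max_x_velocity_post=float(np.max(np.abs(vx[post]))),
        max_y_velocity_post=float(np.max(np.abs(vy[post]))),
        distance_post=_arc_length(sm.x_s[star:hi], y[star:hi]),
        shake_count=float(seg.shake_count),
        shaking_duration_s=seg.shaking_duration_s,
        guarding_duration_s=seg.guarding_duration_s,
    )
    return TrialAnalysis(
        smoothed=sm, window=window, peak=peak, axes=axes,
        displacement=disp, segmentation=seg, features=fv,
    )


def extract_features(traj: Trajectory, config: Config) -> FeatureVector:
    """Extract the 11 named kinematic features from one trajectory."""
    return analyze_trial(traj, config).features


def extract_feature_table(
    trajectories: list[Trajectory], config: Config
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Extract features for many trials; failures become reject records.

    Returns ``(table, rejects)`` where rejects is a list of
    ``(trial_id, reason)`` pairs for trials that raised a TrialError.
    """
    rows = []
    rejects: list[tuple[str, str]] = []
    for traj in trajectories:
        try:
            fv = extract_features(traj, config)
        except TrialError as exc:
            rejects.append((traj.trial_id, f"{type(exc).__name__}: {exc}"))
            continue
        row = {
            "trial_id": traj.trial_id,
            "strain": traj.strain,
            "mouse_id": traj.mouse_id,
            "stimulus": traj.stimulus,
        }
        row.update(fv.as_dict())
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table["stimulus"] = pd.Categorical(
            table["stimulus"], categories=["cs", "db", "lp", "hp"], ordered=True
        )
    return table, rejects


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature means and sample standard deviations (ddof=1)."""

    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for i, name in enumerate(self.feature_names):
            out[name] = (out[name] - self.means[i]) / self.sds[i]
        return out


def zscore_table(
    table: pd.DataFrame, columns: list[str] | tuple[str, ...] | None = None
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Standardize feature columns to mean 0, sample SD 1.

    Raises :class:`~paws.errors.ZeroVarianceError` (naming the feature) on a
    constant column.
    """
    if columns is None:
        from .io import feature_columns

        columns = feature_columns(table)
    if len(table) < 2:
        raise ValueError("need at least 2 rows to standardize")
    means = np.empty(len(columns))
    sds = np.empty(len(columns))
    for i, name in enumerate(columns):
        col = table[name].to_numpy(dtype=float)
        means[i] = col.mean()
        sds[i] = col.std(ddof=1)
        if sds[i] == 0:
            raise ZeroVarianceError(f"feature '{name}' has zero variance")
    params = StandardizationParams(tuple(columns), means, sds)
    return params.apply(table), params
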