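"""Moving principal-axis projection and shaking/guarding segmentation.

Paw shaking is an oscillation whose direction drifts as the limb moves, so a
fixed axis under-measures it.  Instead, for every frame we estimate the
principal axis of paw displacement over a short sliding window (the leading
eigenvector of the 2x2 position covariance), give it a consistent sign by
minimizing the angular deviation from the previous frame's axis, and project
the paw's position (relative to the windowed mean position) onto it.  The
resulting scalar displacement series turns shaking into a simple sequence of
alternating local maxima and minima.

Post-peak segmentation: an inter-extremum swing is supra-threshold when its
magnitude reaches ``shake_threshold_frac`` (default 35%) of the reference
paw height; a maximal run of at least two consecutive supra-threshold swings
is a shaking period.  Guarding is every post-peak frame outside shaking
periods where the paw remains elevated above its final resting height by
more than a small tolerance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import Config
from .errors import ConfigError
from .kinematics import MovementWindow, PeakAnnotation, SmoothedTrajectory

MAX = "max"
MIN = "min"


@dataclass
class AxisSeries:
    """Per-frame unit principal axes and windowed mean positions."""

    axes: np.ndarray        # (n, 2) unit vectors
    mean_x: np.ndarray      # (n,) windowed mean of x_s
    mean_y: np.ndarray      # (n,) windowed mean of y_s
    window_s: float

    def __len__(self) -> int:
        return len(self.axes)


@dataclass(frozen=True)
class Extremum:
    idx: int
    value: float
    kind: str  # MAX or MIN


@dataclass
class DisplacementSeries:
    """Scalar displacement along the moving principal axis, with extrema."""

    times: np.ndarray
    d: np.ndarray
    extrema: list[Extremum]

    def __len__(self) -> int:
        return len(self.d)


@dataclass
class ShakeSegmentation:
    """Shaking and guarding intervals (seconds, half-open) in the post-peak window."""

    shaking_intervals: list[tuple[float, float]]
    guarding_intervals: list[tuple[float, float]]
    shake_count: int
    shaking_duration_s: float
    guarding_duration_s: float


def _windowed_moments(
    x: np.ndarray, y: np.ndarray, window: int
) -> tuple[np.ndarray, ...]:
    """Centered sliding-window first and second moments, truncated at edges."""
    n = len(x)
    half = window // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(lo + window, 0, n)
    lo = np.minimum(lo, hi - 1)  # never empty
    csum = lambda a: np.concatenate(([0.0], np.cumsum(a)))
    sx, sy = csum(x), csum(y)
    sxx, syy, sxy = csum(x * x), csum(y * y), csum(x * y)
    cnt = (hi - lo).astype(float)
    mx = (sx[hi] - sx[lo]) / cnt
    my = (sy[hi] - sy[lo]) / cnt
    cxx = (sxx[hi] - sxx[lo]) / cnt - mx * mx
    cyy = (syy[hi] - syy[lo]) / cnt - my * my
    cxy = (sxy[hi] - sxy[lo]) / cnt - mx * my
    return mx, my, cxx, cyy, cxy


def moving_principal_axis(
    smoothed: SmoothedTrajectory,
    window: MovementWindow | None = None,
    config: Config | None = None,
) -> AxisSeries:
    """Leading eigenvector of the windowed position covariance, per frame.

    Sign consistency: each axis is flipped if its dot product with the
    previous frame's axis is negative; the first axis is oriented to a
    non-negative vertical component.  Zero-variance windows carry the
    previous axis forward (vertical unit vector if at the start).
    """
    if config is None:
        config = Config()
    w = config.axis_window
    if w < 4:
        raise ConfigError(f"axis window spans {w} frames; need >= 4")
    x, y = smoothed.x_s, smoothed.y_s
    n = len(x)
    mx, my, cxx, cyy, cxy = _windowed_moments(x, y, w)

    lam = 0.5 * (cxx + cyy) + np.sqrt(0.25 * (cxx - cyy) ** 2 + cxy**2)
    vx = lam - cyy
    vy = cxy
    norm = np.hypot(vx, vy)
    # covariance nearly isotropic or cxy ~ 0: pick the dominant coordinate axis
    weak = norm <= 1e-12 * np.maximum(lam, 1e-300)
    vx = np.where(weak, np.where(cxx >= cyy, 1.0, 0.0), vx)
    vy = np.where(weak, np.where(cxx >= cyy, 0.0, 1.0), vy)
    norm = np.hypot(vx, vy)
    axes = np.column_stack([vx / norm, vy / norm])

    # zero-variance windows: carry the previous axis forward
    scale = max(float(np.var(x) + np.var(y)), 1e-300)
    still = (cxx + cyy) <= 1e-12 * scale
    if still.any():
        prev = np.array([0.0, 1.0])
        for t in range(n):
            if still[t]:
                axes[t] = prev
            else:
                prev = axes[t]

    # sign consistency via cumulative flips
    if n > 1:
        dots = np.einsum("ij,ij->i", axes[1:], axes[:-1])
        flips = np.cumprod(np.where(dots < 0, -1.0, 1.0))
        axes[1:] *= flips[:, None]
    if axes[0, 1] < 0 or (axes[0, 1] == 0 and axes[0, 0] < 0):
        axes = -axes
    return AxisSeries(axes=axes, mean_x=mx, mean_y=my,
                      window_s=config.axis_window_s)


def _alternating_extrema(
    d: np.ndarray, prune_frac: float, floor_abs: float = 0.0
) -> list[Extremum]:
    """Alternating local maxima/minima of d; plateaus resolve to their first
    frame; swings below ``prune_frac`` of the displacement range are merged."""
    n = len(d)
    if n < 3:
        return []
    change = np.flatnonzero(np.diff(d) != 0.0)
    if change.size < 2:
        return []
    # segment-start representatives: first frame of each distinct-value run
    starts = np.concatenate(([0], change + 1))
    v = d[starts]
    ext: list[Extremum] = []
    for k in range(1, len(starts) - 1):
        rising = v[k] > v[k - 1]
        falling = v[k + 1] < v[k]
        if rising and falling:
            ext.append(Extremum(int(starts[k]), float(v[k]), MAX))
        elif (not rising) and (not falling):
            ext.append(Extremum(int(starts[k]), float(v[k]), MIN))
    floor = max(prune_frac * float(np.max(d) - np.min(d)), floor_abs)
    if floor > 0 and ext:
        ext = _prune_extrema(ext, floor)
        if len(ext) == 1 and float(np.max(d) - np.min(d)) <= floor:
            ext = []
    return ext


def _prune_extrema(ext: list[Extremum], floor: float) -> list[Extremum]:
    """Merge negligible swings (jitter) while preserving alternation."""
    ext = list(ext)
    while len(ext) >= 2:
        swings = [abs(ext[i + 1].value - ext[i].value) for i in range(len(ext) - 1)]
        m = int(np.argmin(swings))
        if swings[m] >= floor:
            break
        if m == 0:
            del ext[0]
        elif m == len(swings) - 1:
            del ext[-1]
        else:
            del ext[m : m + 2]
    return ext


def project_displacement(
    smoothed: SmoothedTrajectory, axes: AxisSeries, config: Config | None = None
) -> DisplacementSeries:
    """Project the paw position onto the moving principal axis.

    ``d_t`` is the signed displacement of the (smoothed) paw position from
    the windowed mean position, along the frame's principal axis.
    """
    if config is None:
        config = Config()
    dx = smoothed.x_s - axes.mean_x
    dy = smoothed.y_s - axes.mean_y
    d = dx * axes.axes[:, 0] + dy * axes.axes[:, 1]
    # dead-band at the position scale's float resolution: a perfectly still
    # paw must not yield rounding-noise extrema
    scale = max(1.0, float(np.max(np.abs(smoothed.x_s))),
                float(np.max(np.abs(smoothed.y_s))))
    ext = _alternating_extrema(d, config.extremum_prune_frac,
                               floor_abs=1e-9 * scale)
    return DisplacementSeries(times=smoothed.times, d=d, extrema=ext)


def _mask_to_intervals(
    mask: np.ndarray, times: np.ndarray, fps: float
) -> list[tuple[float, float]]:
    """Convert a boolean frame mask into half-open [start_s, end_s) intervals."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    out = []
    for a, b in zip(edges[::2], edges[1::2]):
        out.append((float(times[a]), float(times[a] + (b - a) / fps)))
    return out


def segment_shaking_guarding(
    displacement: DisplacementSeries,
    smoothed: SmoothedTrajectory,
    peak: PeakAnnotation,
    window: MovementWindow,
    config: Config,
) -> ShakeSegmentation:
    """Segment the post-peak period [t*, end) into shaking and guarding.

    The swing threshold is ``shake_threshold_frac`` of the reference paw
    height: the baseline-relative maximum smoothed height over the movement
    window (or the raw maximum if ``config.baseline_relative_threshold`` is
    False).  A shaking period is a maximal run of >= 2 consecutive
    supra-threshold swings, spanning its first to last extremum.  The shake
    count is the number of elevated-side displacement extrema (the kind
    found at t*) inside shaking periods.
    Guarding is every other post-peak frame where the paw is elevated above
    its final resting height by more than ``guard_elevation_frac`` of the
    reference height.
    """
    lo, hi = peak.t_star_idx, window.end_idx
    y = smoothed.y_s
    times = smoothed.times
    fps = smoothed.fps
    max_y = float(np.max(y[window.start_idx : window.end_idx]))
    if config.baseline_relative_threshold:
        ref_height = max_y - window.baseline_y
    else:
        ref_height = max_y
    thr = config.shake_threshold_frac * max(ref_height, 0.0)

    # The displacement extremum belonging to the withdrawal peak can land a
    # few frames before t* (smoothing and the moving-mean origin shift it);
    # the post-peak extremum sequence starts at the extremum nearest t*.
    tol = config.axis_window // 2
    post = [e for e in displacement.extrema if lo - tol <= e.idx < hi]
    while len(post) >= 2 and abs(post[1].idx - lo) < abs(post[0].idx - lo):
        post.pop(0)
    if post and post[0].idx < lo and abs(post[0].idx - lo) > tol:
        post.pop(0)
    # The axis sign is only locally consistent, so "maximum of d" is not
    # orientation-invariant.  A paw shake is a return to the elevated
    # position: count extrema of the same kind as the extremum at t*, which
    # is the physically-elevated kind regardless of axis orientation.
    elevated_kind = post[0].kind if post else MAX
    shaking_mask = np.zeros(len(y), dtype=bool)
    shaking_intervals: list[tuple[float, float]] = []
    shake_count = 0
    if len(post) >= 2:
        supra = np.array(
            [abs(post[i + 1].value - post[i].value) >= thr for i in range(len(post) - 1)]
        )
        i = 0
        while i < len(supra):
            if supra[i]:
                j = i
                while j + 1 < len(supra) and supra[j + 1]:
                    j += 1
                if j - i + 1 >= 2:  # at least one full oscillation
                    a, b = max(post[i].idx, lo), post[j + 1].idx
                    shaking_mask[a : b + 1] = True
                    shaking_intervals.append((float(times[a]), float(times[b])))
                    shake_count += sum(
                        1 for e in post[i : j + 2] if e.kind == elevated_kind
                    )
                i = j + 1
            else:
                i += 1

    elevated = y > window.rest_y + config.guard_elevation_frac * max(ref_height, 0.0)
    post_mask = np.zeros(len(y), dtype=bool)
    post_mask[lo:hi] = True
    guard_mask = post_mask & ~shaking_mask & elevated
    guarding_intervals = _mask_to_intervals(guard_mask, times, fps)

    shaking_duration = float(sum(b - a for a, b in shaking_intervals))
    guarding_duration = float(sum(b - a for a, b in guarding_intervals))
    return ShakeSegmentation(
        shaking_intervals=shaking_intervals,
        guarding_intervals=guarding_intervals,
        shake_count=shake_count,
        shaking_duration_s=shaking_duration,
        guarding_duration_s=guarding_duration,
    )


def write_segmentation(seg: ShakeSegmentation, path: str | Path) -> None:
    """Export a segmentation as a 3-column interval CSV for plotting/audit."""
    rows = [(a, b, "shaking") for a, b in seg.shaking_intervals] + [
        (a, b, "guarding") for a, b in seg.guarding_intervals
    ]
    rows.sort()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start_s", "end_s", "label"])
        for a, b, label in rows:
            writer.writerow([f"{a:.17g}", f"{b:.17g}", label])
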