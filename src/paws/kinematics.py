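"""Smoothing, velocity estimation, movement-window and withdrawal-peak detection.

The raw paw position series is smoothed with an order-3 Savitzky-Golay
filter applied independently to x and y; velocities are the analytic first
derivative of the local fitting polynomial, scaled by the frame rate.  Edges
are handled by mirror-padding half a window so the series keeps its length.

The movement window brackets the withdrawal bout: it opens at the first
sustained excursion of speed above a threshold relative to the trial's
maximum speed, and closes once the paw is both slow and settled near its
final resting height for the remainder of the trial.

The withdrawal peak t* is the first paw-height peak inside the movement
window: the earliest downward zero crossing of vertical velocity whose
height prominence clears a floor relative to the trial's maximum
baseline-relative height.  t* splits the trial into the reflexive pre-peak
phase and the affective/attending post-peak phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import peak_prominences, savgol_filter

from .config import Config
from .errors import NoMovementError, NoPeakError, TooShortError
from .io import Trajectory


@dataclass
class SmoothedTrajectory:
    """Savitzky-Golay smoothed positions and velocities for one trial."""

    times: np.ndarray
    x_s: np.ndarray
    y_s: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    fps: float

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class MovementWindow:
    """Half-open frame-index window [start_idx, end_idx) of the withdrawal bout.

    ``baseline_y`` is the pre-movement resting height, ``rest_y`` the final
    resting height after the paw returns to the surface (both on the
    smoothed series).
    """

    start_idx: int
    end_idx: int
    baseline_y: float
    rest_y: float


@dataclass(frozen=True)
class PeakAnnotation:
    """The first paw-height peak t* inside the movement window."""

    t_star_idx: int
    t_star_s: float
    peak_height: float  # y_s(t*) - pre-movement baseline


def smooth(traj: Trajectory, config: Config) -> SmoothedTrajectory:
    """Apply the Savitzky-Golay smoother and derivative to a trajectory."""
    window = config.sg_window
    if len(traj) < window:
        raise TooShortError(
            f"trajectory has {len(traj)} frames; smoothing window is {window}"
        )
    delta = 1.0 / traj.fps
    x_s = savgol_filter(traj.x, window, config.sg_order, mode="mirror")
    y_s = savgol_filter(traj.y, window, config.sg_order, mode="mirror")
    vx = savgol_filter(traj.x, window, config.sg_order, deriv=1, delta=delta,
                       mode="mirror")
    vy = savgol_filter(traj.y, window, config.sg_order, deriv=1, delta=delta,
                       mode="mirror")
    speed = np.hypot(vx, vy)
    return SmoothedTrajectory(
        times=traj.times, x_s=x_s, y_s=y_s, vx=vx, vy=vy, speed=speed,
        fps=traj.fps,
    )


def _final_rest_y(y_s: np.ndarray, config: Config) -> float:
    """Final resting height: median of the trailing axis-window frames."""
    k = min(len(y_s), max(config.axis_window, 3))
    return float(np.median(y_s[-k:]))


def _baseline_y(y_s: np.ndarray, start_idx: int) -> float:
    """Pre-movement baseline height: median of frames before movement onset."""
    if start_idx <= 0:
        return float(y_s[0])
    return float(np.median(y_s[:start_idx]))


def detect_movement_window(
    smoothed: SmoothedTrajectory, config: Config
) -> MovementWindow:
    """Find the frame window containing the withdrawal bout.

    Start: first frame opening a run of >= 3 consecutive frames with speed
    above ``max(movement_speed_frac * max(speed), movement_speed_min)``.
    End: one past the last frame at which the paw is still fast or still
    elevated more than ``guard_elevation_frac`` of the peak height above its
    final resting y.
    """
    speed = smoothed.speed
    n = len(speed)
    thr = max(config.movement_speed_frac * float(np.max(speed)),
              config.movement_speed_min)
    above = speed > thr
    # first index starting a run of >= 3 True values
    sustained = above[:-2] & above[1:-1] & above[2:] if n >= 3 else np.array([])
    starts = np.flatnonzero(sustained)
    if starts.size == 0:
        raise NoMovementError(
            f"no sustained movement above speed threshold {thr:.6g}"
        )
    start_idx = int(starts[0])

    baseline = _baseline_y(smoothed.y_s, start_idx)
    rest_y = _final_rest_y(smoothed.y_s, config)
    peak_h = float(np.max(smoothed.y_s) - baseline)
    tol = config.guard_elevation_frac * max(peak_h, 0.0)

    settled = (speed < thr) & (np.abs(smoothed.y_s - rest_y) <= tol)
    unsettled = np.flatnonzero(~settled[start_idx:])
    if unsettled.size == 0:
        end_idx = min(start_idx + 1, n - 1)
    else:
        end_idx = min(start_idx + int(unsettled[-1]) + 1, n - 1)
    if end_idx <= start_idx:
        end_idx = min(start_idx + 1, n - 1)
    return MovementWindow(
        start_idx=start_idx, end_idx=end_idx, baseline_y=baseline, rest_y=rest_y
    )


def _snap_to_local_max(y: np.ndarray, idx: int, lo: int, hi: int) -> int:
    """Walk ``idx`` uphill to the nearest local maximum of y within [lo, hi)."""
    i = idx
    while i + 1 < hi and y[i + 1] > y[i]:
        i += 1
    while i - 1 >= lo and y[i - 1] > y[i]:
        i -= 1
    return i


def find_first_peak(
    smoothed: SmoothedTrajectory, window: MovementWindow, config: Config
) -> PeakAnnotation:
    """Locate t*, the first qualifying paw-height peak in the movement window.

    Candidates are frames where the smoothed vertical velocity crosses zero
    from positive to negative; the earliest candidate whose height
    prominence is at least ``peak_prominence_frac`` of the maximum
    baseline-relative height qualifies.
    """
    y = smoothed.y_s
    vy = smoothed.vy
    lo, hi = window.start_idx, window.end_idx
    baseline = window.baseline_y
    max_rel_height = float(np.max(y[lo:hi]) - baseline)
    prom_floor = config.peak_prominence_frac * max(max_rel_height, 0.0)

    seg = vy[lo:hi]
    crossings = np.flatnonzero((seg[:-1] > 0) & (seg[1:] <= 0)) + lo
    # residual tracker jitter decorates a broad apex with micro-maxima, so a
    # crossing frame itself can be a negligible wiggle; take the highest
    # point within half a smoothing window of the crossing instead
    h = config.sg_window // 2
    seen: set[int] = set()
    for c in crossings:
        a, b = max(lo, c - h), min(hi, c + h + 1)
        cand = a + int(np.argmax(y[a:b]))
        cand = _snap_to_local_max(y, cand, lo, hi)
        if cand in seen:
            continue
        seen.add(cand)
        is_local_max = (cand == 0 or y[cand] >= y[cand - 1]) and (
            cand == len(y) - 1 or y[cand] >= y[cand + 1]
        )
        if not is_local_max:
            continue
        prom = float(peak_prominences(y, [cand])[0][0])
        if prom >= prom_floor and prom > 0:
            return PeakAnnotation(
                t_star_idx=int(cand),
                t_star_s=float(smoothed.times[cand]),
                peak_height=float(y[cand] - baseline),
            )
    raise NoPeakError(
        f"no paw-height peak with prominence >= {prom_floor:.6g} in movement window"
    )
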