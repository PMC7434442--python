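"""Class-conditioned synthetic withdrawal trajectories with ground truth.

The generator emulates the phenomenology of hind-paw withdrawal captured on
high-speed video: innocuous stimuli (cotton swab ``cs``, dynamic brush
``db``) evoke a single smooth up-down arc, while noxious stimuli (light and
heavy pinprick ``lp``/``hp``) evoke a faster, higher lift followed by an
oscillatory shaking train and an elevated guarding plateau before the paw
returns to the surface.  Trajectories are built from raised-cosine segments
between knots (zero velocity at every knot, so extrema are well defined),
sampled on the frame grid, with i.i.d. Gaussian tracker jitter added to both
coordinates.  Every trial is fully determined by its seed.

Ground truth records what the generator programmed — peak height, shake
count (number of displacement maxima in the shaking train, including the
withdrawal peak), guard duration, movement bounds — computed on the clean,
noise-free signal, so extraction accuracy can be measured exactly.

A second generator draws feature tables directly from a proportional-odds
model with known coefficients and cutpoints, for parameter-recovery and
cross-validation tests of the ordinal scale.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .config import Config
from .io import STIMULI, Trajectory


@dataclass
class GroundTruth:
    """What the generator programmed for one trial."""

    stim_class: str
    peak_height: float
    shake_count: int
    shake_freq_hz: float
    shake_amp_frac: float
    guard_duration_s: float
    movement_start_s: float
    movement_end_s: float
    t_star_s: float
    noise_sd: float

    def to_dict(self) -> dict:
        return asdict(self)


# Class-conditioned defaults: peak height (spatial units ~ mm), rise time to
# the withdrawal peak (s), shake count range (displacement maxima incl. the
# peak), guard plateau hold (s), lateral sweep amplitude (units).  Heights
# and latencies follow the qualitative ordering of evoked withdrawals
# (innocuous: low, slow arcs; noxious: high, fast, 20-130 ms latencies, with
# shaking near 20 Hz and guarding up to ~1 s).
_CLASS_DEFAULTS: dict[str, dict] = {
    "cs": dict(height=(4.0, 0.8), rise=(0.090, 0.015), shakes=(0, 0),
               guard=(0.0, 0.0), sweep=(0.5, 0.2)),
    "db": dict(height=(6.0, 1.0), rise=(0.070, 0.012), shakes=(0, 0),
               guard=(0.0, 0.0), sweep=(6.0, 1.0)),
    "lp": dict(height=(12.0, 2.0), rise=(0.035, 0.006), shakes=(2, 4),
               guard=(0.30, 0.08), sweep=(2.0, 0.8)),
    "hp": dict(height=(16.0, 2.5), rise=(0.025, 0.004), shakes=(4, 8),
               guard=(0.60, 0.15), sweep=(2.0, 0.8)),
}

_SHAKE_FREQ = (20.0, 1.5)   # Hz (mean, sd)
# Oscillation amplitude as a fraction of peak height.  Chosen so that a
# programmed shake is unambiguous under the 35%-of-peak-height swing
# criterion: the moving-mean origin of the displacement projection
# attenuates a sinusoid at frequency f by 1 - sinc(f * window_s), ~0.5-0.8
# for 13-25 Hz shakes with the default 0.04 s window, so swings of 0.8 * H
# stay well above 0.35 * H across the whole frequency range.
_SHAKE_AMP_FRAC = 0.8
_GUARD_HEIGHT_FRAC = 0.3    # guard plateau height as a fraction of peak height
_NOISE_SD = 0.05            # tracker jitter SD in spatial units
_REST_BEFORE = 0.15         # s of pre-stimulus rest
_REST_AFTER = 0.30          # s of post-return rest
_DESC_TO_GUARD = 0.10       # s, descent from last shake maximum to the plateau
_DESC_TO_FLOOR = 0.15       # s, final descent to the surface


def _render_knots(knots: list[tuple[float, float]], times: np.ndarray) -> np.ndarray:
    """Piecewise raised-cosine interpolation through (time, value) knots."""
    y = np.full_like(times, knots[0][1])
    for (t0, v0), (t1, v1) in zip(knots[:-1], knots[1:]):
        if t1 <= t0:
            continue
        mask = (times >= t0) & (times < t1)
        u = (times[mask] - t0) / (t1 - t0)
        y[mask] = v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * u))
    y[times >= knots[-1][0]] = knots[-1][1]
    return y


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > low:
            return float(v)
    return max(mean, low + sd)


def simulate_withdrawal(
    stim_class: str,
    seed: int | None = None,
    config: Config | None = None,
    peak_height: float | None = None,
    rise_s: float | None = None,
    n_shakes: int | None = None,
    shake_freq_hz: float | None = None,
    shake_amp_frac: float = _SHAKE_AMP_FRAC,
    guard_hold_s: float | None = None,
    noise_sd: float = _NOISE_SD,
    trial_id: str = "",
    strain: str = "",
    mouse_id: str = "",
) -> tuple[Trajectory, GroundTruth]:
    """Generate one synthetic withdrawal trial with known ground truth.

    Class-conditioned defaults can be overridden per argument.  The returned
    :class:`GroundTruth` carries the programmed quantities measured on the
    clean signal (before tracker noise is added).
    """
    if stim_class not in STIMULI:
        raise ValueError(f"stim_class must be one of {list(STIMULI)}, got {stim_class!r}")
    if config is None:
        config = Config()
    fps = config.fps
    if fps <= 0:
        raise ValueError("fps must be positive")
    rng = np.random.default_rng(seed)
    d = _CLASS_DEFAULTS[stim_class]

    H = peak_height if peak_height is not None else _truncated_normal(
        rng, *d["height"], low=0.5)
    rise = rise_s if rise_s is not None else _truncated_normal(
        rng, *d["rise"], low=0.008)
    k_lo, k_hi = d["shakes"]
    k = n_shakes if n_shakes is not None else int(rng.integers(k_lo, k_hi + 1))
    if k == 1:
        k = 2  # a single oscillation already has two displacement maxima
    freq = shake_freq_hz if shake_freq_hz is not None else _truncated_normal(
        rng, *_SHAKE_FREQ, low=8.0)
    guard = guard_hold_s if guard_hold_s is not None else (
        _truncated_normal(rng, *d["guard"], low=0.0) if d["guard"][0] > 0 else 0.0)
    sweep = _truncated_normal(rng, *d["sweep"], low=0.0)

    t_lift = _REST_BEFORE
    t_peak = t_lift + rise
    amp = shake_amp_frac * H

    knots: list[tuple[float, float]] = [(0.0, 0.0), (t_lift, 0.0), (t_peak, H)]
    if k >= 2:
        half = 1.0 / (2.0 * freq)
        for j in range(1, 2 * (k - 1) + 1):
            v = H - amp if j % 2 == 1 else H
            knots.append((t_peak + j * half, v))
        t_train_end = knots[-1][0]
        if guard > 0:
            knots.append((t_train_end + _DESC_TO_GUARD, _GUARD_HEIGHT_FRAC * H))
            knots.append((t_train_end + _DESC_TO_GUARD + guard, _GUARD_HEIGHT_FRAC * H))
            knots.append((knots[-1][0] + _DESC_TO_FLOOR, 0.0))
        else:
            knots.append((t_train_end + _DESC_TO_FLOOR, 0.0))
    else:
        if guard > 0:
            knots.append((t_peak + _DESC_TO_GUARD, _GUARD_HEIGHT_FRAC * H))
            knots.append((t_peak + _DESC_TO_GUARD + guard, _GUARD_HEIGHT_FRAC * H))
            knots.append((knots[-1][0] + _DESC_TO_FLOOR, 0.0))
        else:
            knots.append((t_peak + _DESC_TO_FLOOR, 0.0))

    t_end = knots[-1][0] + _REST_AFTER
    n = int(np.ceil(t_end * fps)) + 1
    times = np.arange(n) / fps
    y_clean = _render_knots(knots, times)

    # lateral component: a slow there-and-back sweep spanning the movement
    x_knots = [(0.0, 0.0), (t_lift, 0.0),
               (0.5 * (t_lift + knots[-1][0]), sweep), (knots[-1][0], 0.0)]
    x_clean = _render_knots(x_knots, times)

    truth = _ground_truth(
        stim_class, times, x_clean, y_clean, H, k, freq, shake_amp_frac,
        guard, t_peak, knots, config, noise_sd,
    )

    x = x_clean + rng.normal(0.0, noise_sd, size=n)
    y = y_clean + rng.normal(0.0, noise_sd, size=n)
    traj = Trajectory(
        times=times, x=x, y=y, fps=fps, trial_id=trial_id, strain=strain,
        mouse_id=mouse_id, stimulus=stim_class, spatial_unit="a.u.",
    )
    return traj, truth


def _ground_truth(
    stim_class: str,
    times: np.ndarray,
    x_clean: np.ndarray,
    y_clean: np.ndarray,
    H: float,
    k: int,
    freq: float,
    amp_frac: float,
    guard: float,
    t_peak: float,
    knots: list[tuple[float, float]],
    config: Config,
    noise_sd: float,
) -> GroundTruth:
    """Programmed quantities measured on the clean signal."""
    fps = config.fps
    vx = np.gradient(x_clean) * fps
    vy = np.gradient(y_clean) * fps
    speed = np.hypot(vx, vy)
    thr = config.movement_speed_frac * float(np.max(speed))
    above = speed > thr
    runs = np.flatnonzero(above[:-2] & above[1:-1] & above[2:])
    start_idx = int(runs[0]) if runs.size else 0
    tol = config.guard_elevation_frac * H
    settled = (speed < thr) & (np.abs(y_clean) <= tol)
    unsettled = np.flatnonzero(~settled[start_idx:])
    end_idx = start_idx + int(unsettled[-1]) + 1 if unsettled.size else start_idx + 1
    end_idx = min(end_idx, len(times) - 1)

    if k >= 2:
        t_train_end = t_peak + 2 * (k - 1) / (2.0 * freq)
    else:
        t_train_end = t_peak
    star_idx = int(np.round(t_peak * fps))
    train_end_idx = int(np.round(t_train_end * fps))
    elevated = y_clean > tol
    post = np.zeros(len(times), dtype=bool)
    post[star_idx:end_idx] = True
    in_train = np.zeros(len(times), dtype=bool)
    in_train[star_idx : train_end_idx + 1] = k >= 2
    guard_truth = float(np.sum(post & elevated & ~in_train)) / fps

    return GroundTruth(
        stim_class=stim_class,
        peak_height=H,
        shake_count=k if k >= 2 else 0,
        shake_freq_hz=freq if k >= 2 else 0.0,
        shake_amp_frac=amp_frac if k >= 2 else 0.0,
        guard_duration_s=guard_truth,
        movement_start_s=float(times[start_idx]),
        movement_end_s=float(times[end_idx]),
        t_star_s=t_peak,
        noise_sd=noise_sd,
    )


def simulate_cohort(
    n_strains: int = 8,
    mice_per_strain: int = 10,
    seed: int = 0,
    config: Config | None = None,
    classes: tuple[str, ...] = STIMULI,
    strain_height_sd: float = 0.05,
) -> tuple[list[Trajectory], list[GroundTruth]]:
    """Simulate a full study: every mouse receives each stimulus once.

    Strains differ by a mild multiplicative factor on peak height
    (lognormal-ish, SD ``strain_height_sd``), mimicking modest
    between-strain kinematic variation.
    """
    if config is None:
        config = Config()
    rng = np.random.default_rng(seed)
    trajectories: list[Trajectory] = []
    truths: list[GroundTruth] = []
    for s in range(n_strains):
        strain = f"strain{s:02d}"
        height_factor = float(np.exp(rng.normal(0.0, strain_height_sd)))
        for m in range(mice_per_strain):
            mouse = f"m{m:02d}"
            for stim in classes:
                trial_seed = int(rng.integers(0, 2**31 - 1))
                mu, sd = _CLASS_DEFAULTS[stim]["height"]
                h = _truncated_normal(rng, mu * height_factor, sd, low=0.5)
                traj, truth = simulate_withdrawal(
                    stim, seed=trial_seed, config=config, peak_height=h,
                    trial_id=f"{strain}_{mouse}_{stim}", strain=strain,
                    mouse_id=mouse,
                )
                trajectories.append(traj)
                truths.append(truth)
    return trajectories, truths


def simulate_feature_cohort(
    n_strains: int = 8,
    mice_per_strain: int = 10,
    beta_star: np.ndarray | list[float] | None = None,
    cutpoints_star: np.ndarray | list[float] | None = None,
    seed: int = 0,
    trials_per_mouse: int = 4,
    feature_names: tuple[str, ...] | None = None,
    strain_shifts: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw a feature table from a known proportional-odds model.

    Standardized features are i.i.d. standard normal per trial; the ordinal
    label is drawn from ``P(y <= j) = logistic(c_j - beta . z)`` at the
    given coefficients and cutpoints.  ``strain_shifts`` optionally adds a
    mean shift (in SD units) to a strain's features *after* labels are
    drawn, creating an outlier strain whose features mismatch its labels.

    Returns ``(table, latent_scores)``.
    """
    from scipy.special import expit

    if beta_star is None:
        beta_star = np.array([1.5, 1.0, 0.75, 0.5, 1.0, 0.75, 0.5])
    beta_star = np.asarray(beta_star, dtype=float)
    if cutpoints_star is None:
        cutpoints_star = np.array([-2.0, 0.0, 2.0])
    cutpoints_star = np.asarray(cutpoints_star, dtype=float)
    if np.any(np.diff(cutpoints_star) <= 0):
        raise ValueError("cutpoints_star must be strictly increasing")
    kf = len(beta_star)
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(kf))
    if len(feature_names) != kf:
        raise ValueError("feature_names length must match beta_star")
    n_classes = len(cutpoints_star) + 1
    labels = STIMULI[:n_classes]

    rng = np.random.default_rng(seed)
    rows = []
    latents = []
    for s in range(n_strains):
        strain = f"strain{s:02d}"
        for m in range(mice_per_strain):
            mouse = f"m{m:02d}"
            for t in range(trials_per_mouse):
                z = rng.normal(size=kf)
                sc = float(z @ beta_star)
                cum = expit(cutpoints_star - sc)
                y = int(np.searchsorted(cum, rng.random()))
                if strain_shifts and strain in strain_shifts:
                    z = z + np.asarray(strain_shifts[strain], dtype=float)
                row = {
                    "trial_id": f"{strain}_{mouse}_t{t}",
                    "strain": strain,
                    "mouse_id": mouse,
                    "stimulus": labels[y],
                }
                row.update({n: float(v) for n, v in zip(feature_names, z)})
                rows.append(row)
                latents.append(sc)
    table = pd.DataFrame(rows)
    table["stimulus"] = pd.Categorical(
        table["stimulus"], categories=list(STIMULI), ordered=True
    )
    return table, np.asarray(latents)
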