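import numpy as np
import pytest
from scipy.signal import find_peaks, peak_prominences

from paws import (
    Config,
    ConfigError,
    NoMovementError,
    NoPeakError,
    Trajectory,
    detect_movement_window,
    find_first_peak,
    simulate_withdrawal,
    smooth,
)
from tests.conftest import gaussian_bump_trajectory

FPS = 2000.0


def _traj(y, x=None, fps=FPS):
    n = len(y)
    t = np.arange(n) / fps
    if x is None:
        x = np.zeros(n)
    return Trajectory(times=t, x=x, y=np.asarray(y, float), fps=fps)


class TestSmooth:
    def test_constant_series_reproduced_with_zero_velocity(self, config):
        traj = _traj(np.full(500, 7.25), x=np.full(500, -3.0))
        sm = smooth(traj, config)
        np.testing.assert_allclose(sm.x_s, -3.0, atol=1e-9)
        np.testing.assert_allclose(sm.y_s, 7.25, atol=1e-9)
        assert np.max(np.abs(sm.vx)) < 1e-9
        assert np.max(np.abs(sm.vy)) < 1e-9

    def test_linear_ramp_velocity_exact_in_interior(self, config):
        t = np.arange(1000) / FPS
        sm = smooth(_traj(3.0 * t), config)
        h = config.sg_window // 2
        np.testing.assert_allclose(sm.vy[h:-h], 3.0, rtol=1e-9)

    def test_cubic_reproduced_exactly_by_order3_filter(self, config):
        # an order-3 Savitzky-Golay fit reproduces cubics; oracle = direct
        # polynomial evaluation
        t = np.arange(2000) / FPS
        y = (10 * t) ** 3 + 1.0
        sm = smooth(_traj(y), config)
        h = config.sg_window // 2
        np.testing.assert_allclose(sm.y_s[h:-h], y[h:-h], rtol=1e-10)

    def test_window_not_exceeding_order_is_config_error(self):
        with pytest.raises(ConfigError):
            Config(sg_window_s=0.001, fps=2000.0)  # 3-frame window, order 3


class TestMovementWindow:
    def test_window_brackets_single_bump(self, config):
        traj = gaussian_bump_trajectory(center=0.5, sigma=0.05)
        sm = smooth(traj, config)
        win = detect_movement_window(sm, config)
        apex = int(0.5 * FPS)
        assert win.start_idx < apex < win.end_idx
        assert traj.y[win.start_idx] < 0.1 * traj.y.max()

    def test_subthreshold_jitter_raises_no_movement(self):
        cfg = Config(movement_speed_min=1000.0)
        rng = np.random.default_rng(0)
        traj = _traj(rng.normal(0, 0.01, 2000))
        sm = smooth(traj, cfg)
        with pytest.raises(NoMovementError):
            detect_movement_window(sm, cfg)

    def test_simulator_bounds_recovered_within_5_frames(self, config):
        traj, truth = simulate_withdrawal(
            "hp", seed=11, config=config, n_shakes=5, shake_freq_hz=20.0,
            noise_sd=0.0,
        )
        sm = smooth(traj, config)
        win = detect_movement_window(sm, config)
        assert abs(win.start_idx - truth.movement_start_s * FPS) <= 5
        assert abs(win.end_idx - truth.movement_end_s * FPS) <= 5


class TestFirstPeak:
    def test_single_bump_apex_found_within_one_frame(self, config):
        traj = gaussian_bump_trajectory(center=0.1, sigma=0.02, duration=0.4)
        sm = smooth(traj, config)
        win = detect_movement_window(sm, config)
        peak = find_first_peak(sm, win, config)
        assert peak.t_star_s == pytest.approx(0.1, abs=1.0 / FPS)
        assert peak.peak_height == pytest.approx(10.0, rel=0.01)

    def test_sine_on_plateau_first_crest(self, config):
        t = np.arange(int(0.3 * FPS) + 1) / FPS
        y = 5.0 + np.sin(2 * np.pi * 10.0 * t)
        sm = smooth(_traj(y), config)
        win = detect_movement_window(sm, config)
        peak = find_first_peak(sm, win, config)
        assert peak.t_star_s == pytest.approx(0.025, abs=2.0 / FPS)

    def test_low_prominence_bump_skipped_matches_bruteforce(self, config):
        # small leading bump (8% prominence) must be skipped for the big one;
        # oracle = brute-force local-maximum scan with the same rule
        t = np.arange(int(1.0 * FPS)) / FPS
        y = (0.8 * np.exp(-0.5 * ((t - 0.25) / 0.02) ** 2)
             + 10.0 * np.exp(-0.5 * ((t - 0.5) / 0.05) ** 2))
        y += 0.08 * 10.0 * np.exp(-0.5 * ((t - 0.3) / 0.01) ** 2)
        sm = smooth(_traj(y), config)
        win = detect_movement_window(sm, config)
        peak = find_first_peak(sm, win, config)

        seg = sm.y_s[win.start_idx : win.end_idx]
        cand, _ = find_peaks(seg)
        proms = peak_prominences(seg, cand)[0]
        floor = config.peak_prominence_frac * (seg.max() - win.baseline_y)
        expected = cand[proms >= floor][0] + win.start_idx
        assert peak.t_star_idx == expected
        assert abs(peak.t_star_s - 0.5) < 0.01

    def test_no_qualifying_peak_raises(self, config):
        # monotone rise that never comes back down inside the window still
        # has a trivial "peak" at the end but no downward vy crossing
        t = np.arange(2000) / FPS
        y = 10 * t
        sm = smooth(_traj(y), config)
        win = detect_movement_window(sm, config)
        with pytest.raises(NoPeakError):
            find_first_peak(sm, win, config)


class TestInvariants:
    def test_translation_invariance(self, config):
        traj, _ = simulate_withdrawal("lp", seed=3, config=config)
        shifted = Trajectory(times=traj.times, x=traj.x + 123.4,
                             y=traj.y + 56.7, fps=traj.fps)
        win1 = detect_movement_window(smooth(traj, config), config)
        win2 = detect_movement_window(smooth(shifted, config), config)
        assert (win1.start_idx, win1.end_idx) == (win2.start_idx, win2.end_idx)
        p1 = find_first_peak(smooth(traj, config), win1, config)
        p2 = find_first_peak(smooth(shifted, config), win2, config)
        assert p1.t_star_idx == p2.t_star_idx
        assert p1.peak_height == pytest.approx(p2.peak_height, abs=1e-9)

    def test_time_reversal_maps_last_peak_to_first(self, config):
        # two equal bumps: reversing the series must find the mirrored
        # image of the later bump as the first peak
        t = np.arange(int(1.2 * FPS)) / FPS
        y = (10 * np.exp(-0.5 * ((t - 0.3) / 0.04) ** 2)
             + 10 * np.exp(-0.5 * ((t - 0.8) / 0.04) ** 2))
        fwd = _traj(y)
        rev = _traj(y[::-1].copy())
        n = len(y)
        sm_r = smooth(rev, config)
        win_r = detect_movement_window(sm_r, config)
        peak_r = find_first_peak(sm_r, win_r, config)
        assert abs((n - 1 - peak_r.t_star_idx) - 0.8 * FPS) <= 3

    def test_vy_crosses_zero_within_one_frame_of_t_star(self, config):
        traj, _ = simulate_withdrawal("hp", seed=9, config=config)
        sm = smooth(traj, config)
        win = detect_movement_window(sm, config)
        peak = find_first_peak(sm, win, config)
        i = peak.t_star_idx
        window = sm.vy[max(i - 1, 0) : i + 2]
        assert window.min() <= 0 <= window.max()
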