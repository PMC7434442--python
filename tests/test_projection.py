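import numpy as np
import pytest

from paws import (
    Config,
    DisplacementSeries,
    MovementWindow,
    PeakAnnotation,
    SmoothedTrajectory,
    Trajectory,
    moving_principal_axis,
    project_displacement,
    segment_shaking_guarding,
    simulate_withdrawal,
    smooth,
    write_segmentation,
)
from paws.projection import _alternating_extrema

FPS = 2000.0


def _smoothed(y, x=None, fps=FPS):
    n = len(y)
    if x is None:
        x = np.zeros(n)
    t = np.arange(n) / fps
    vx = np.gradient(x) * fps
    vy = np.gradient(y) * fps
    return SmoothedTrajectory(times=t, x_s=np.asarray(x, float),
                              y_s=np.asarray(y, float), vx=vx, vy=vy,
                              speed=np.hypot(vx, vy), fps=fps)


class TestMovingPrincipalAxis:
    def test_pure_vertical_oscillation_gives_vertical_axis(self, config):
        t = np.arange(1000) / FPS
        sm = _smoothed(np.sin(2 * np.pi * 25 * t), x=np.full(1000, 2.0))
        axes = moving_principal_axis(sm, config=config)
        np.testing.assert_allclose(axes.axes[:, 0], 0.0, atol=1e-9)
        np.testing.assert_allclose(np.abs(axes.axes[:, 1]), 1.0, atol=1e-9)

    def test_pure_horizontal_sweep_gives_horizontal_axis(self, config):
        t = np.arange(1000) / FPS
        sm = _smoothed(np.zeros(1000), x=np.sin(2 * np.pi * 25 * t))
        axes = moving_principal_axis(sm, config=config)
        np.testing.assert_allclose(np.abs(axes.axes[:, 0]), 1.0, atol=1e-9)

    def test_unit_norm_and_sign_consistency(self, config):
        traj, _ = simulate_withdrawal("hp", seed=5, config=config)
        sm = smooth(traj, config)
        axes = moving_principal_axis(sm, config=config)
        norms = np.linalg.norm(axes.axes, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        dots = np.einsum("ij,ij->i", axes.axes[1:], axes.axes[:-1])
        assert np.all(dots >= 0)

    def test_circular_path_axis_tracks_tangent(self, config):
        # window (0.04 s) much shorter than the period (1 s): the principal
        # axis of a short arc is its chord ~ tangent.  Oracle: brute-force
        # eigendecomposition of every windowed covariance.
        t = np.arange(2000) / FPS
        theta = 2 * np.pi * t  # 1 Hz circle
        x, y = 5 * np.cos(theta), 5 * np.sin(theta)
        sm = _smoothed(y, x=x)
        axes = moving_principal_axis(sm, config=config)

        w = config.axis_window
        half = w // 2
        for i in range(100, 1900, 137):
            lo, hi = max(0, i - half), min(len(t), i - half + w)
            pts = np.column_stack([x[lo:hi], y[lo:hi]])
            cov = np.cov(pts.T, bias=True)
            evals, evecs = np.linalg.eigh(cov)
            lead = evecs[:, np.argmax(evals)]
            cos = abs(float(axes.axes[i] @ lead))
            assert cos > 0.99999
            tangent = np.array([-np.sin(theta[i]), np.cos(theta[i])])
            ang = np.degrees(np.arccos(min(abs(float(axes.axes[i] @ tangent)), 1.0)))
            assert ang < 5.0


class TestProjectDisplacement:
    def test_vertical_sine_recovers_amplitude_and_extrema(self, config):
        # 25 Hz: the 0.04 s windowed mean of a full period vanishes, so the
        # projected displacement keeps the full amplitude A
        A, f = 2.5, 25.0
        t = np.arange(4000) / FPS
        sm = _smoothed(A * np.sin(2 * np.pi * f * t), x=np.zeros(4000))
        axes = moving_principal_axis(sm, config=config)
        disp = project_displacement(sm, axes, config)
        interior = disp.d[200:-200]
        assert np.max(np.abs(interior)) == pytest.approx(A, rel=0.01)
        kinds = [e.kind for e in disp.extrema]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))  # alternate
        # crest spacing = one period
        maxima = [e.idx for e in disp.extrema if e.kind == "max"]
        spacing = np.diff(maxima)
        np.testing.assert_allclose(spacing, FPS / f, atol=2)

    def test_constant_position_zero_displacement_no_extrema(self, config):
        sm = _smoothed(np.full(1000, 3.3), x=np.full(1000, 1.1))
        axes = moving_principal_axis(sm, config=config)
        disp = project_displacement(sm, axes, config)
        np.testing.assert_allclose(disp.d, 0.0, atol=1e-12)
        assert disp.extrema == []

    def test_simulator_oscillations_give_2k_extrema(self, config):
        k = 5
        traj, truth = simulate_withdrawal(
            "hp", seed=21, config=config, n_shakes=k, shake_freq_hz=20.0,
            noise_sd=0.0,
        )
        sm = smooth(traj, config)
        axes = moving_principal_axis(sm, config=config)
        disp = project_displacement(sm, axes, config)
        star = int(round(truth.t_star_s * FPS))
        train_end = star + int(round(2 * (k - 1) / (2 * 20.0) * FPS))
        n_ext = sum(1 for e in disp.extrema
                    if star - 40 <= e.idx <= train_end + 40)
        assert abs(n_ext - (2 * k - 1)) <= 1


def _segmentation_fixture(d_post, y_post_level=0.6, n_pre=200, peak_idx=None):
    """Build segmentation inputs around a given post-peak displacement array.

    The trial has baseline 0, a reference peak height of 1.0 at the peak
    frame, and stays elevated at ``y_post_level`` for the post-peak span.
    """
    n_post = len(d_post)
    n = n_pre + n_post
    t = np.arange(n) / FPS
    y = np.concatenate([np.linspace(0, 1.0, n_pre), np.full(n_post, y_post_level)])
    y[n_pre - 1] = 1.0
    sm = _smoothed(y)
    d = np.concatenate([np.zeros(n_pre), d_post])
    ext = _alternating_extrema(d, 0.0)
    disp = DisplacementSeries(times=t, d=d, extrema=ext)
    window = MovementWindow(start_idx=0, end_idx=n - 1, baseline_y=0.0, rest_y=0.0)
    peak = PeakAnnotation(t_star_idx=n_pre - 1, t_star_s=t[n_pre - 1], peak_height=1.0)
    return disp, sm, peak, window


class TestSegmentation:
    def test_15hz_halfheight_oscillation_counts_six_shakes(self, config):
        # 0.4 s of A=0.5 sine at 15 Hz: swings of 2A = 1.0 x peak height,
        # all supra-threshold -> one shaking period with 15 * 0.4 = 6 crests
        t_post = np.arange(int(0.4 * FPS)) / FPS
        d_post = 0.5 * np.sin(2 * np.pi * 15.0 * t_post)
        disp, sm, peak, window = _segmentation_fixture(d_post)
        seg = segment_shaking_guarding(disp, sm, peak, window, config)
        assert seg.shake_count == 6
        assert len(seg.shaking_intervals) == 1
        assert seg.shaking_duration_s == pytest.approx(0.4, abs=0.05)

    def test_subthreshold_oscillation_is_guarding_only(self, config):
        # swings of 2 x 0.15 = 0.3 < 0.35 never open a shaking period; the
        # elevated post-peak span counts as guarding
        t_post = np.arange(int(0.4 * FPS)) / FPS
        d_post = 0.15 * np.sin(2 * np.pi * 15.0 * t_post)
        disp, sm, peak, window = _segmentation_fixture(d_post)
        seg = segment_shaking_guarding(disp, sm, peak, window, config)
        assert seg.shake_count == 0
        assert seg.shaking_intervals == []
        assert seg.guarding_duration_s == pytest.approx(0.4, abs=0.02)

    def test_monotone_descent_guarding_while_elevated_only(self, config):
        # descent from peak to floor with no extrema: no shaking; guarding
        # covers only the frames above the elevation tolerance
        n_post = int(0.4 * FPS)
        d_post = np.zeros(n_post)
        disp, sm, peak, window = _segmentation_fixture(d_post)
        y_desc = np.linspace(1.0, 0.0, n_post)
        sm.y_s[-n_post:] = y_desc
        seg = segment_shaking_guarding(disp, sm, peak, window, config)
        assert seg.shake_count == 0
        frac_above = np.mean(y_desc > 0.05)
        assert seg.guarding_duration_s == pytest.approx(0.4 * frac_above, abs=0.02)

    def test_shake_count_zero_iff_duration_zero(self, config):
        for seed in range(6):
            traj, _ = simulate_withdrawal(
                ["cs", "db", "lp", "hp"][seed % 4], seed=seed, config=config)
            from paws.features import analyze_trial
            seg = analyze_trial(traj, config).segmentation
            assert (seg.shake_count == 0) == (seg.shaking_duration_s == 0.0)
            for (a1, b1) in seg.shaking_intervals:
                for (a2, b2) in seg.guarding_intervals:
                    assert b1 <= a2 or b2 <= a1  # disjoint

    @pytest.mark.parametrize("scale", [0.05, 1.0, 37.5])
    def test_scale_invariance_of_segmentation(self, config, scale):
        traj, _ = simulate_withdrawal("hp", seed=13, config=config, n_shakes=4)
        scaled = Trajectory(times=traj.times, x=traj.x * scale,
                            y=traj.y * scale, fps=traj.fps)
        from paws.features import analyze_trial
        seg1 = analyze_trial(traj, config).segmentation
        seg2 = analyze_trial(scaled, config).segmentation
        assert seg1.shake_count == seg2.shake_count
        np.testing.assert_allclose(seg1.shaking_intervals, seg2.shaking_intervals)
        np.testing.assert_allclose(seg1.guarding_intervals, seg2.guarding_intervals)

    def test_shake_count_matches_ground_truth_on_seeded_trials(self, config):
        hits, total = 0, 40
        for s in range(total):
            traj, truth = simulate_withdrawal("hp", seed=3000 + s, config=config)
            from paws.features import analyze_trial
            seg = analyze_trial(traj, config).segmentation
            assert abs(seg.shake_count - truth.shake_count) <= 1
            hits += seg.shake_count == truth.shake_count
        assert hits / total >= 0.95

    def test_interval_csv_export(self, config, tmp_path, hp_trial):
        from paws.features import analyze_trial
        traj, _ = hp_trial
        seg = analyze_trial(traj, config).segmentation
        p = tmp_path / "seg.csv"
        write_segmentation(seg, p)
        lines = p.read_text().strip().splitlines()
        assert lines[0] == "start_s,end_s,label"
        labels = {line.split(",")[2] for line in lines[1:]}
        assert labels <= {"shaking", "guarding"}
        assert len(lines) >= 2
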