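# Methods

This note documents the model and the numerical choices behind `paws`:
what each pipeline stage computes, which parameters matter and why their
defaults are what they are, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## Pipeline

### Input model

A trial is a uniformly sampled paw-position time series (frame index, x, y)
in camera coordinates, at a known frame rate (default 2000 fps, i.e. 0.5 ms
per frame; typical trials span 2–3 s ≈ 5000 frames).  x is
anterior/posterior displacement, y vertical height with larger = higher.
Trackers that use image coordinates (down-positive y) are handled by an
explicit `invert_y` flag that reflects y about its maximum; we deliberately
do not auto-detect orientation, because a silent flip is untestable.  The
spatial unit (pixels or calibrated mm) is left as-is: all features are
reported in input units, and standardization removes the scale before any
modeling, so none of the downstream statistics depend on calibration.

### Smoothing and velocities

x(t) and y(t) are smoothed independently with an order-3 Savitzky–Golay
filter; velocities are the analytic first derivative of the local cubic
fit, scaled by the frame rate.  Window: 0.0105 s (21 frames at 2000 fps,
forced odd).  Rationale: long enough to suppress frame-level tracker
jitter, short enough to pass paw-shaking oscillations (≈ 15–25 Hz) almost
unattenuated.  Edges are mirror-padded by half a window so the series keeps
its length; derivative estimates in the outer half-window are therefore
unreliable, which is immaterial because trials begin and end at rest.

### Movement window

The withdrawal bout opens at the first frame starting ≥ 3 consecutive
frames with speed above `movement_speed_frac` (default 0.05) × the trial's
maximum speed; requiring a sustained run rejects isolated jitter spikes.
It closes after the last frame at which the paw is either fast (above that
threshold) or still elevated above its final resting height by more than
`guard_elevation_frac` (default 0.05) × the peak height.  The final resting
height is the median of the trailing 0.04 s; the pre-movement baseline is
the median height before the start frame.  Because the speed threshold is
relative, a recording that contains only noise still has a "maximum speed";
an optional absolute floor (`movement_speed_min`, default 0 = disabled)
lets users with a known tracker noise magnitude get a clean
"no movement detected" error instead.

### Withdrawal peak t*

t\* is the first paw-height peak inside the movement window: candidate
frames where the smoothed vertical velocity crosses zero downward, resolved
to the highest point within half a smoothing window (residual jitter
decorates a broad apex with micro-maxima; without this, every candidate is
a negligible wiggle), and accepted if the height prominence is at least
`peak_prominence_frac` (default 0.10) × the maximum baseline-relative
height.  The prominence floor is our construction — some rejection rule is
needed against jitter peaks, and 10% of the trial's own amplitude is scale
free.  Peak height is measured from the pre-movement baseline (not the
floor, not absolute camera y); this is one of the genuinely open choices
and is exposed through the window's recorded baseline.

### Principal-axis projection

For every frame, the principal axis a_t is the leading eigenvector of the
2×2 covariance of smoothed position over a centered sliding window of
`axis_window_s` = 0.04 s (truncated at the series edges; computed in closed
form from the 2×2 covariance).  Eigenvectors have no intrinsic sign, and
displacement measured along a sign-flipping axis is meaningless, so each
axis is flipped to have non-negative dot product with its predecessor; the
first axis is oriented vertically upward (ties toward +x).  Zero-variance
windows (paw perfectly still) carry the previous axis forward, vertical at
the start.  The scalar displacement d_t is the paw's offset from the
windowed mean position, projected on a_t.

Two consequences of this construction are worth knowing.  First, the
moving-mean origin acts as a high-pass filter: a pure sinusoid of frequency
f survives with amplitude factor 1 − sinc(f · 0.04 s) — ≈ 0.5 at 15 Hz,
1.0 at 25 Hz — so slow, small oscillations contribute less displacement
than their raw amplitude.  Second, the axis orientation at any given time
is path-dependent (jitter at rest random-walks it), so no quantity may
depend on the global sign of d; see shake counting below.

### Extrema and segmentation

Alternating local maxima/minima of d_t are found by a turning-point scan;
plateaus resolve to their first frame.  Adjacent extremum pairs whose swing
is below `extremum_prune_frac` (default 0.01) × the displacement range —
tracker jitter riding a large movement — are merged before alternation, and
swings below float resolution at the position scale are discarded outright,
so a motionless paw yields no extrema.

Post-peak segmentation, on [t\*, end): the extremum sequence starts at the
extremum nearest t\* (the displacement image of the withdrawal peak lands a
few frames early because of smoothing and the moving-mean origin).  An
inter-extremum swing |d(e_{i+1}) − d(e_i)| is supra-threshold when it
reaches `shake_threshold_frac` (default 0.35) × the reference paw height —
by default the baseline-relative maximum smoothed height over the movement
window; a config switch (`baseline_relative_threshold=False`) uses the raw
maximum instead, since either reading of "maximum paw height" is
defensible.  A shaking period is a maximal run of ≥ 2 consecutive
supra-threshold swings (one full oscillation; a single large swing is a
movement, not a shake), spanning its first to last extremum.  The shake
count is the number of extrema *of the same kind as the t\* extremum*
inside shaking periods: the t\* extremum is physically "paw elevated", so
this counts returns to the elevated position and is invariant to the
arbitrary axis orientation, where "count the maxima" is not.  Guarding is
every post-peak frame outside shaking periods with height above the final
resting height by more than `guard_elevation_frac` × reference height;
note this includes the transit of a smoothly returning paw, so even an
innocuous-arc trial accrues a small guarding duration (≈ 0.1 s).

### Features

Eleven features per trial: {max baseline-relative height, max |vx|,
max |vy|, path length} over the pre-peak window [start, t\*] and over the
post-peak window [t\*, end), plus shake count and shaking/guarding
durations.  Velocities use absolute values so mirror-image camera placement
cannot change a feature.  Post-peak height/velocity maxima are computed
over the post-peak window only by default (`post_window_only`), the other
open reading (whole trial) being a config switch.  Downstream modeling uses
either the 4 pre-peak features (reflexive phase only) or the 7 post-peak
features; all 11 are always stored.

## Ordinal pain scale

Features are standardized (mean 0, sample SD 1, ddof = 1; parameters stored
and reapplied to new data).  A proportional-odds cumulative-logit model
over cs < db < lp < hp is fit by maximum likelihood (BFGS, gradient
tolerance 1e-8, ≤ 500 iterations, via statsmodels' ordinal model).  The
proportional-odds assumption — one coefficient vector shared across
cutpoints — is what makes the score univariate; it is an assumption, not a
fact about the data.  If the optimizer fails or a coefficient on
standardized features exceeds 10 in magnitude (odds ratios beyond e¹⁰ per
SD only arise under quasi-separation), the fit is retried once with a ridge
penalty of 1e-6 on β and a `separation` warning is recorded; small-n
subsets (single strains, CV folds) do separate in practice.  A condition
number above 1e8 on the standardized design records a `collinear` warning.
With fewer than four classes present only the realized cutpoints are
estimated, and the rescaling anchors exist only when the relevant
boundaries (db|lp, lp|hp) do.

Scores: s = β·z; rescaled s′ = (s − c₂)/(c₃ − c₂), so s′ = 0 at the
no-pain/pain boundary and 1 at the low/high-pain boundary by construction
(exactly, at machine precision — the rescaling is affine in the fitted
cutpoints).  Binary prediction is s > c₂; the ordinal class prediction is
the argmax of the cumulative-logit class probabilities.  Feature importance
is β sorted by magnitude; loadings are per-SD and comparable across
features only because of standardization.

## Validation

Cross-validation folds are mice (identified by strain × mouse id) or whole
strains.  Standardization and the ordinal fit are redone inside every
training fold — fitting them once globally would leak held-out information.
Folds whose training set lacks a stimulus class are skipped with a warning
and their trials marked unevaluated, not imputed.  Accuracy is the fraction
of evaluated held-out trials with correct binary prediction.

The bootstrap CI resamples the per-trial correctness indicators with
replacement (default 10,000 resamples, seeded) and takes the 2.5th/97.5th
percentiles.  The resampling unit is the trial, not the mouse: with
hundreds of trials the trial-level percentile interval matches the binomial
normal approximation, which is the scale on which the accuracy itself is
defined.  The null model assigns binary classes with their empirical
probabilities ignoring features; its expected accuracy is Σ_c p_c², and a
seeded stochastic realization is returned alongside.  Strain comparisons
use Welch's unequal-variance t-test on per-trial correctness indicators
(Welch–Satterthwaite df); per-trial, not per-mouse, because the question is
about trial-level decoding accuracy and the trial counts set the df.

## Synthetic data

The generator emulates the phenomenology of evoked hind-paw withdrawals,
with class-conditioned defaults chosen once as realistic murine values:

| class | peak height (units) | rise to peak (s) | shakes | guard hold (s) |
|---|---|---|---|---|
| cs | 4.0 ± 0.8 | 0.090 ± 0.015 | 0 | 0 |
| db | 6.0 ± 1.0 | 0.070 ± 0.012 | 0 | 0 |
| lp | 12 ± 2 | 0.035 ± 0.006 | 2–4 | 0.30 ± 0.08 |
| hp | 16 ± 2.5 | 0.025 ± 0.004 | 4–8 | 0.60 ± 0.15 |

Shake frequency 20 ± 1.5 Hz; shake amplitude 0.8 × peak height (chosen so
a programmed shake is unambiguous under the 35% swing criterion after the
moving-mean attenuation across the whole frequency range — at 0.5 × H a
15 Hz shake would hover at the threshold and "ground-truth shake count"
would stop being well defined); guard plateau at 0.3 × peak height;
i.i.d. Gaussian tracker jitter with SD 0.05 units on both coordinates
(sub-pixel scale); db adds a lateral there-and-back sweep.  Trajectories
are piecewise raised-cosine segments between knots, so every extremum has
zero velocity and the clean signal is C¹.  Ground truth (movement bounds,
guarding duration) is measured on the clean pre-noise signal with the same
threshold definitions, because that is the quantity the segmentation
estimates; programmed shake count includes the withdrawal peak as the first
elevated extremum.

What the generator does **not** emulate: tracking dropouts and outlier
frames (switchable off by default is none at all), perspective distortion
of the 45°-ish camera, multi-bout trials (paw lifted twice with full rest
between — the pipeline analyzes the first bout only), biomechanics, and —
importantly — realistic between-class overlap.  Simulated classes separate
almost perfectly in feature space, so cross-validated accuracies near 100%
on synthetic cohorts demonstrate that the machinery is correct, not that
real recordings would score that high; real cohorts overlap and the same
code measures that overlap.  The feature-table generator (standard-normal
features, labels drawn from a known proportional-odds model) exists to test
coefficient recovery and cross-validation calibration, where the generating
parameters are the oracle.

## Degenerate inputs and tie-breaks

Non-uniform or non-increasing time stamps, mismatched column lengths and
non-positive frame rates are rejected at construction.  Trials that are too
short, show no sustained movement, or have no qualifying peak raise typed
trial errors that batch drivers convert to reject records (the run
continues, exit code 0, rejects listed with reasons).  Zero-variance
feature columns fail standardization by name.  Plateau extrema resolve to
the plateau's first frame; equal-height peak candidates resolve to the
earliest.  Model JSON serializes floats with shortest round-trip
representation, so save → load reproduces every coefficient bit-exactly;
CSV reading uses round-trip float parsing for the same reason.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
a 320-trial trajectory cohort (8 strains × 10 mice × 4 stimuli) for
cross-validation, 200 heavy-pinprick trials for extraction fidelity, and a
400-trial feature table for coefficient recovery — sizes matched to the
cohort scale the pipeline is designed for, with seeds fixed by the caller.

## Known limitations

- The proportional-odds model forces a single direction in feature space;
  stimulus classes that differ qualitatively (not monotonically) would
  violate it silently.
- The 35% shaking threshold and the moving-mean origin jointly impose an
  effective high-pass: slow (< ~10 Hz), small oscillations are guarding,
  not shaking, by definition.
- Guarding includes return-transit time above the elevation tolerance, so
  it is a few tens of milliseconds even for brisk innocuous withdrawals.
- Only the first movement bout per trial is analyzed.
- Accuracy comparisons across strains inherit the usual caveats of
  per-trial independence assumptions (trials within a mouse are treated as
  exchangeable by the bootstrap and Welch units).
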