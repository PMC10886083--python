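# Methods

## Problem and model

`gaitkin` quantifies how well 2D human-pose-estimation (HPE) landmarks from a
single video camera reproduce sagittal lower-extremity kinematics measured by
marker-based motion capture during treadmill walking, and how that agreement
depends on where the camera stands. The analysis chain is: landmark I/O and
body-frame normalization → smoothing/gap filling → joint angles → gait events
and cycles → two-system agreement (MAE, Pearson ρ) aggregated over a cohort by
joint × side × camera position.

### Joint-angle model

Four segments per side are directed 2D vectors in a y-up, anterior-positive-x
body frame: trunk (shoulder→hip), thigh (hip→knee), shank (knee→ankle), foot
(ankle→toe). Segment orientation is the quadrant-correct arctangent
φ = atan2(Δy, Δx); joint angles are differences of adjacent segment angles,

    θ_hip = φ_thigh − φ_trunk,
    θ_knee = φ_thigh − φ_shank,
    θ_ankle = φ_foot − φ_shank − 90°.

Directions are fixed so quiet standing gives 0° at all three joints with
flexion/dorsiflexion positive. The two-argument arctangent is essential: a
plain arctan is ambiguous by 180° whenever a segment crosses vertical (the
shank does every swing phase). Traces are unwrapped (period 360°) before any
analysis. The heel landmark never enters the angle computation — it drives
event detection only. Because both measurement systems pass through the same
angle code, any global sign convention cancels in the agreement metrics.

The pixel-to-body-frame flip (image y points down) is auto-detected from
anatomy — shoulders above hips, toes anterior of heels — rather than
configured, which makes the mapping robust to camera side/mirroring and
idempotent.

### Events and cycles

On a treadmill there is no net translation, so heel strike is taken at local
maxima of the heel's anterior excursion relative to the ipsilateral hip, and
toe-off at the minimum of the toe excursion between consecutive heel strikes.
Computing toe-off per heel-strike interval (rather than by an independent peak
search) enforces the strict heel-strike/toe-off alternation by construction;
the choice is recorded in `GaitEvents.method`. Candidate heel strikes must be
separated by ≥ 0.5× the median cycle period (configurable). Cycles outside
50–150% of the median cycle length are dropped as event artifacts. Cycles are
time-normalized to a 101-point 0–100% grid; ensemble SD uses the population
estimator so that duplicating the cycle list leaves both mean and SD unchanged
(a descriptive spread, not an inferential one).

### Agreement statistics

MAE = (1/N)Σ|M_i − H_i| and the sample Pearson correlation are computed over
the full aligned trial (~50–60 cycles), after the reference stream is
resampled (linear interpolation) to the camera frame rate and both streams are
cropped at their first detected left heel strike. Frames with unfilled
landmark dropouts are excluded pairwise; zero-variance traces raise an error
rather than returning a silent 0. Cohort tables report across-subject mean ±
sample (n−1) SD per joint × side × position. The camera-position effect is
tested per joint × side with a one-way repeated-measures ANOVA
(F = MS_position/MS_error, df = (k−1), (k−1)(n−1)) on the complete
subject × position MAE grid; a grid with zero between-position variation
returns the boundary p = 1. The ANOVA is computed directly from sums of
squares for speed and well-defined degenerate behavior; the test suite
cross-checks it against statsmodels' AnovaRM and a permutation F-test.

## Synthetic study generator

The generator emulates the validation-study conditions: ~1-minute treadmill
trials at self-selected cadence, a 120 fps reference stream, and 30 fps
cameras at 3 m distance and 0.8 m height at five azimuths on the subject's
left.

* **Trajectories.** Hip/knee/ankle angles are truncated Fourier series (3
  harmonics) over cycle phase, right leg offset half a cycle. Defaults give
  gait-like ranges (hip ≈ −10…+30°, knee ≈ 0…65°, ankle ≈ −15…+12°); they are
  fixture constants, not claims about any cohort. Per-subject sampling jitters
  cadence (uniform 0.85–1.15 cycles/s), stature (±3%), amplitudes (±8%) and
  offsets (±1.5°).
* **Forward kinematics.** The trunk is fixed vertical at the origin (treadmill
  frame); legs chain segment directions exactly inverse to the angle
  equations, so recomputing angles from a lateral projection recovers the
  inputs to float precision. Ground-truth event times are the frames nearest
  the phase of extreme anterior heel/toe excursion of the analytic model.
* **Camera.** Pinhole (default, focal 1500 px, portrait 1080×2340) or
  orthographic (600 px/m, used for exact round-trip and foreshortening
  checks). Azimuth 90° is a pure side view. Under an orthographic oblique view
  a sagittal segment at elevation φ projects to atan2(sin φ, cos φ·cos α) for
  azimuth deviation α — the foreshortening law the tests verify.
* **Position labels.** P1…P5 map by default to azimuths 70/80/90/100/110°
  (front-diagonal → lateral → rear). A raw geometric projection has no learned
  pose prior: at steeply oblique views it compresses segment elevation angles
  far more than a trained landmark detector, which infers joint positions from
  appearance and is substantially view-tolerant. Moderate default deviations
  keep the simulated observations in the same error regime as real HPE output
  (all-position mean MAE < 5°); steeper geometry is one `CameraConfig` field
  away.
* **Noise/occlusion.** Gaussian pixel jitter with per-position, per-landmark-
  group SDs: proximal landmarks (shoulder/hip/knee) are cleanest at the front
  diagonal P2 (1.2 px) and foot landmarks at the lateral P3 (1.2 px), both
  degrading toward the rear (up to 8 px at P5 at ≈600 px/m). The camera-far
  side gets 1.6× the near-side SD; while the projected feet overlap
  (separation < 40 px) the far side's SD is additionally tripled and its
  landmarks drop out with probability 0.1–0.3 (rear positions highest),
  emulating crossover occlusion of the far leg. These defaults *are* the
  simulated study conditions; they were chosen once to reproduce the
  qualitative structure the generator must emulate (best hip/knee agreement at
  the front diagonal, best ankle agreement laterally, far side worse, rear
  worst for the far ankle).

### What the generator does not emulate

Real HPE errors are temporally correlated, appearance-dependent (clothing,
lighting), and biased rather than zero-mean Gaussian; soft-tissue artifact and
marker wobble on the reference side are absent; the treadmill frame excludes
overground progression. Passing tests therefore demonstrate the correctness
of the *pipeline* and the recoverability of planted effects under controlled
conditions — not the field accuracy of any particular pose estimator.

## Numerical choices

* Wrapping to (−180°, 180°] before unwrapping; antisymmetric wrap keeps 180°
  (not −180°).
* Moving average: centered, truncated (shrinking) window at edges and around
  NaNs, length-preserving; default 5 frames at 30 fps (~0.17 s), attenuating
  jitter while passing gait-band (<6 Hz) content. Interior full-window samples
  preserve periodic means exactly; edge samples do not (truncation bias
  O(amplitude·window/length)).
* Gap filling: linear, interior gaps ≤ 10 frames by default; leading/trailing
  gaps held at the nearest value; longer gaps stay flagged and are excluded
  pairwise downstream.
* Resampling: linear interpolation onto t₀ + k/fps; no anti-alias prefilter
  (gait energy is far below the 15 Hz Nyquist of the 30 fps target).
* fps inferred from CSV timestamps is snapped to the nearest integer when
  within 0.01 to absorb serialization round-off.
* Alignment is integer-frame at a shared heel strike; no sub-frame
  cross-correlation.

## Problem sizes

The packaged study runs 10 synthetic subjects × 5 positions × 60 s (≈50
trials, 1800 frames each at 30 fps, 7200 at 120 fps), which the full pipeline
processes in a few seconds; the null-calibration check of the ANOVA uses 500
replicates of a 10 × 5 grid.

## Known limitations

* Sagittal plane only; no frontal/transverse angles or 3D kinematics.
* Event detection assumes treadmill (pelvis-relative excursions); overground
  walking would need a different convention.
* The occlusion model is statistical (noise inflation + dropout), not
  geometric ray casting; it reproduces the far-side error asymmetry with two
  interpretable parameters but no appearance effects.
* The repeated-measures ANOVA assumes sphericity; no correction is applied.
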