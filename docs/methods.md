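# Methods

## The measurement model

Intrinsic-signal optical imaging under red (630 nm) illumination records
cortical reflectance with a 12-bit camera.  Increased local neural
activity raises deoxyhemoglobin concentration, which absorbs red light:
pixels *darken* (fractional reflectance change ΔR/R goes negative) with a
hemodynamic lag of seconds.  Trials are imaged for 7 s at 10 frames/s
starting 1 s before the Go Cue.  Frame timestamps mark the **end** of
each 0.1-s exposure (−0.9 … +6.0 s), which makes the canonical analysis
windows exact frame sets: baseline = the 10 frames with t ≤ 0,
post-movement = the 39 frames in [+2.2, +6.0] s, and the 33-frame
[+2.8, +6.0] s variant.  The 5-frame peak window is defined by count —
five consecutive frames ending at a configurable time (default +4.4 s) —
because a nominal "[+4.1, +4.4] s" span contains only four 0.1-s frames
under any stamp convention.

## Synthetic study conditions

The simulator generates everything the pipeline consumes, with hidden
truth exported for recovery testing.  Its defaults *are* the study
conditions the pipeline is validated on; they were fixed once and are not
per-test knobs.

**Geometry.** 128×128 px at 10 px/mm (12.8-mm field of view; the
acquisition hardware it emulates runs at 50 px/mm — kernel sizes quoted
in native pixels are scaled by that 1/5 ratio when filtering simulated
frames).  The motor map is a nested somatotopy: a hand (digits/wrist)
core inside an arm (shoulder/elbow) surround in M1 (thresholds 8–28 µA),
premotor territory rostral of a border 4.5 mm from the central sulcus
(thresholds 35–110 µA), trunk medially, face laterally, a PMd forelimb
zone, and a small PMv forelimb zone that the overlap analysis must
exclude.  ICMS sites sit on a jittered 0.75-mm grid (~225 penetrations).

**Response model.** Five circular patches (≈30 % of the forelimb
representation) carry zone-specific ΔR/R time courses built from
Gaussian lobes, normalized to a unit negative peak and zero at and
before the Cue: *arm* profiles have a positive lobe during
movement/hold (peak +1.7 s, σ 0.5 s, half amplitude) followed by a
negative peak; *hand* profiles are flat until the negative peak ramps
up (~+2.5 s onward); *vessel* pixels carry an early negative transient
(peak +1.2 s).  Patch negative peaks realize the three observed
peak-time classes: early (+2.0 s, modelled as a pure dip so its
observable minimum equals its nominal time), intermediate (+3.5 s), and
late (+5.5 s).

**Amplitudes.** The paper-scale peak |ΔR/R| is ~1e-3; no numeric
amplitudes are printed in the source literature, so these are free
parameters, not claims about any real dataset.  Shared (arm-zone)
patches use nearly equal amplitudes across movement conditions
(1.2 / 1.2 / 1.1 × 1e-3 for precision / power / reach-only) — reach and
transport engage the arm about equally in all three conditions — while
grasp-selective patches carry the condition differences
(1.2 / 0.6 / 0.1 × 1e-3).  This matches the qualitative behavioural
observations the simulator must reproduce (arm kinematics nearly
identical across grips; digit use nearly absent in reach-only) and has
two consequences by construction: the grasp/shared amplitude *ratio*
falls monotonically (1.0, 0.5, ~0.09), which makes precision ×
reach-only the most dissimilar movement pair in every frame's spatial
pattern, and every patch stays active in every movement condition, so
movement-pair correlations never collapse to zero at any post-movement
frame.  Withhold amplitudes are identically zero.

**Noise and artifacts.** Per-pixel, per-frame Gaussian noise with
SD = 1.5e-3 in reflectance units (slightly above the signal peak — a
single raw frame shows no visible response, as in real ISOI).  The base
image is a smooth texture (5-px correlation length, 5 % contrast) with
dark vessel tracks (35 % absorption, optically blurred); texture
gradients are kept gentle deliberately, so that sub-pixel resampling
error during jitter simulation and correction stays well below the
response amplitude.  Per-frame rigid jitter is uniform ±1 px; a motion
artifact adds a ≤3-px shift for 0.2 s at movement onset.  Session-to-
session geometry differences are smooth quadratic displacement fields
(≤6 px by default, capped at 15 px) with 25–60 exported landmark pairs.

**Behavioural data.** EMG (2 kHz) is a condition-scaled Gaussian burst
envelope times a white-noise carrier over a 2-µV floor; an optional 8-Hz,
6-µV sinusoid injects artifact with analytic 1–14 Hz band power of
18 µV², above the 7-µV² screen.  Kinematics (480 Hz) place two rigid LED
triads and rotate the distal one through a programmed angle sweep —
about the z axis for flexion-type angles, about the segment axis for
pronation — so marker-derived angles equal the programmed curve to
machine precision.  Condition peak amplitudes are ordered
precision > power > reach-only for both modalities.

**What the simulator does not model** (and hence what green tests do not
establish about real recordings): cardiac/respiratory oscillations,
photon shot noise (noise is Gaussian, not Poisson), realistic vascular
trees, non-stationary illumination, slow drifts, behavioural variability
in movement timing, and the observation-condition experiments.

## Pipeline numerics

* **Rigid alignment**: FFT phase correlation with mean removal and a
  Hann window (suppresses the wrap-around edge bias), run twice — the
  window multiplicatively shrinks the estimate by a few percent of the
  shift, so a second pass re-estimates the residual after correcting the
  first guess.  Sub-pixel refinement at 1/50 px; accuracy ≈0.1 px on
  simulated frames at 8-px jitter.  Correction resamples with a cubic
  spline.
* **Exclusion rule**: any frame out of register by >10 px (native)
  excludes the trial; the log records the worst frame.
* **ΔR/R**: the mean of the pre-Cue frames is subtracted *and divided*
  (the standard ISOI convention); a flag restores plain subtraction.
  Non-positive baseline pixels raise with coordinates.
* **Spatial filtering**: high-pass = frame − median(frame) with a square
  window of side 251 native px (odd-forced), the median computed on a
  4×-downsampled image purely as an accelerator; then Gaussian smoothing
  with σ = window/3 (window 5 native px).  Reflect padding.  "Kernel =
  N pixels" is read as the window side; window vs radius vs σ is not
  defined by the conventions this pipeline follows, so both are
  configurable.
* **Session registration**: displacement field = global affine (least
  squares on landmark pairs) + multilevel B-spline approximation of the
  residuals (control lattices refined 1→2→4… cells per side, 5 levels by
  default).  The affine term makes translations exactly representable,
  which a finite B-spline hierarchy alone is not.  Landmark residual RMS
  is reported; a Jacobian-determinant check on a test grid guards
  against folding.  Alignment applies the first-order inverse (sampling
  at p − d(p)), valid for the small smooth warps being corrected.
* **Pixelwise test**: pooled-variance two-sample *t* (Welch by flag);
  left tail = darkening.  Zero-variance pixels get p = 1 and are logged.
  Bonferroni divides alpha by the vessel-excluded forelimb pixel count.
  Component denoising is 8-connected by default (4 by flag) and removes
  components of ≤10 pixels.
* **Peak-time maps**: per-pixel argmin over the post-Cue window; ties
  break to the earliest frame; pixels that never go negative are
  invalid.  Temporal smoothing before the argmin is available but off by
  default.
* **Zero-lag correlation**: Pearson over the flattened vessel-excluded
  forelimb pixels (centered); an uncentered cosine variant is behind a
  flag since centering conventions vary.
* **ANOVA**: scipy one-way ANOVA with Bonferroni-corrected pairwise
  *t*-tests; parametric screens (Bartlett variance comparability,
  skewness and excess kurtosis in [−1, 1]) are computed and reported,
  not enforced.
* **AUC**: trapezoidal, Cue to end of withdrawal; z-scored within
  session × signal across all that session's trials (sample SD;
  population-SD via flag); per-condition summary = median across
  trials; group summaries are trial-count-weighted means.

## Validation experiment sizes

The bundled validation experiments (tests and `scripts/acceptance.py`)
run at desk scale: null calibration on 200 signal-free 128×128 trials;
patch recovery on the default 4 × 50-trial session with full
registration and filtering; condition contrasts on two simulated
subjects × 4 conditions × 50 trials (jitter disabled there — the
contrast analysis consumes trial-averaged series and registration
accuracy is validated separately); behaviour on 30 trials per condition;
determinism on a 64-px, 20–30-trial demo run executed twice.  The null
calibration runs on baseline-normalized but spatially *unfiltered*
stacks: smoothing correlates neighbouring pixels, which would invalidate
the independent-pixel binomial band on the significant-pixel count while
leaving per-pixel calibration intact.

## Known limitations

* The overlap of a thresholded map exceeds the generating patch area by
  a thin boundary ring whose width grows with trial count (edge pixels
  of a smoothed step cross the fixed significance threshold); at the
  default 50 trials the bias is ≈1 px of perimeter.
* The M1 border polyline is a rasterized class boundary; where no
  low/high threshold transition falls inside the 3–5 mm central-sulcus
  band, the band check reports violations rather than resolving them.
* The PMd/PMv divide is an input (a medial–lateral split line), not
  inferred from the data.
* The first-order warp inverse limits cross-session alignment accuracy
  to O(‖∇d‖·‖d‖) — ≈0.3 px for the default ≤6-px fields.
* Pooled-variance *t*-tests assume comparable variances; the simulator
  satisfies this, and Welch's test is available where real data might
  not.
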