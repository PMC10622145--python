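# isoimap

Analysis pipeline for **intrinsic-signal optical imaging (ISOI) of
reach-to-grasp activity in motor cortex**, for researchers who map
movement-related cortical activity against intracortical-microstimulation
(ICMS) motor maps.

Under red (630 nm) illumination, pixel *darkening* (negative fractional
reflectance change, ΔR/R) lags increases in neural activity.  Given
trial-structured image stacks (70 frames at 10 frames/s, acquisition from
−1.0 s before the Go Cue), the pipeline:

1. **simulates** sessions with known ground truth (hemodynamic "patches"
   inside a nested hand-in-arm forelimb somatotopy, vessel dynamics, rigid
   jitter, motion artifact, session warps, EMG and 3-D marker data);
2. **preprocesses** trials: rigid alignment (phase correlation), exclusion
   of trials out of register by >10 px, ΔR/R conversion against the 10
   pre-Cue frames, high-pass median filtering (kernel = 250 native px) and
   Gaussian smoothing, and landmark-based non-rigid session registration
   (global affine + multilevel B-spline approximation);
3. **builds motor maps**: Voronoi tiles clipped to 0.75 mm, consolidated
   classes (digits/wrist → hand, shoulder/elbow → arm), the M1 border at
   the <30 µA threshold transition 3–5 mm from the central sulcus, and a
   rasterized forelimb-representation mask;
4. **thresholds activity maps** with a pixelwise two-sample *t*-test of
   movement frames (+2.2…+6.0 s, *n* = 39, or a 5-frame window) against
   baseline frames across trials (left tail *p* < 1e−4, optional Bonferroni
   correction by the forelimb pixel count), removes components of ≤10
   connected pixels, and reports map size as **percent overlap** with the
   forelimb representation — plus ROI time courses, per-frame map-size
   series, and per-pixel peak-time maps;
5. **contrasts conditions** via paired *t*-maps (*p* < 0.001) and zero-lag
   correlation of time-matched trial-averaged frames over the forelimb
   mask (39 post-movement coefficients per pair, pooled across subjects),
   with one-way ANOVA and Bonferroni-corrected post hoc *t*-tests;
6. **quantifies forelimb use**: EMG artifact screening (>7 µV² in 1–14 Hz
   drops the trial), rectified envelopes (zero-phase 100-ms window), joint
   angles from LED marker triads, >2 %-dropout screening, trapezoidal AUC
   from Cue to end of withdrawal, per-session z-scoring, and trial-weighted
   group summaries.

## Worked example

`examples/` contains one narrative script per capability.  The end-to-end
run (`python examples/07_full_pipeline.py`) prints:

```
stages run: simulate, preprocess, map, contrast, behavior, report
trials per condition: {'precision': 16, 'power': 16, 'reach-only': 16, 'withhold': 16}
excluded trials: 0
  thresholded map   precision:   7.9% of forelimb
  thresholded map       power:   2.9% of forelimb
  thresholded map  reach-only:   2.0% of forelimb
  thresholded map    withhold:   0.0% of forelimb
  pair        precision|power: mean r = +0.304
  pair   precision|reach-only: mean r = +0.236
  pair     precision|withhold: mean r = -0.004
  pair       power|reach-only: mean r = +0.230
  pair         power|withhold: mean r = -0.014
  pair    reach-only|withhold: mean r = +0.023
AUC ANOVA: F = 28797.1, p = 2.29e-86
```

Reading this: the three movement conditions produce patchy maps that
overlap a limited fraction of the forelimb representation while the
no-movement control stays at 0 % (at this small demo size — 16 trials per
condition on a 9.6-mm field — the *t*-test detects only patch cores; the
default 50-trial sessions recover the full ~30 % patch coverage).
Movement conditions correlate with each other far more than with
withhold, and the AUC ANOVA recovers the precision > power > reach-only
ordering of forelimb use.

A thin CLI wraps the same pipeline:

```bash
isoimap all --seed 5 --outdir demo_run
isoimap validate --config demo_run/resolved_config.yaml
```

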