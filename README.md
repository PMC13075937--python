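# idiofly

Tracking and individuality statistics for walking and flying *Drosophila*
across environmental contexts.

Individual flies show stable, fly-specific behavioral tendencies — some walk
more, fixate visual objects harder, or hug the arena wall more than their
genetically identical siblings. The scientific question this package serves
is whether those idiosyncrasies *persist* when the environment changes: over
days, temperatures, light conditions, arena geometries, and even across the
switch from walking to tethered flight. `idiofly` implements the full
analysis chain for that question, and ships a synthetic-data layer so every
stage can be validated end-to-end against known ground truth without any
recordings.

## What it does

**Tracking.**
- *Walking*: single-fly centroid tracking in back-lit arenas (single 120 mm
  platform, 5×5 arrays of 49 mm arenas, Y-maze arrays). Background model =
  per-pixel max of first and last frame; per frame, the background-subtracted
  image is thresholded inside each ROI and the centroid stored. Multiple
  blobs → nearest to the previous position; no blob → last position held.
  ROIs are found by adaptive thresholding + area filtering and sorted
  row-major; lens distortion is corrected by a Brown–Conrady remap.
- *Flight*: 0–360° heading of a magneto-tethered fly from silhouette video.
  Two Gaussian blur scales separate body from appendages; the body's
  second-moment ellipse gives an axis in [0, 180°); the head is the body
  half with the smaller pixel sum, extending the heading to [0, 360°);
  visible wings mark non-flying frames.

**Behavioral parameters.** % time walked and walking speed (after a
0.8 mm/frame position-update filter), vector strength
R = |n⁻¹ Σₖ e^{iθₖ}| (angles doubled for axial, two-stripe geometry),
signed/absolute angular velocity, centrophobicity (time outside 80% of the
arena radius; 0.36 under uniform occupancy), pause counts, axial median
heading, occupancy heatmaps capped at the 95%-quantile of nonzero bin
counts, and non-mover exclusion.

**Individuality statistics.** Cross-context Pearson correlations;
within-group percentile ranks (0–100) and absolute rank changes; a
ridge-regularised GLM predicting rank change from binary which-factor-changed
predictors (λ by 5-fold CV over a log-spaced 10⁻⁶–10⁶ grid, coefficients
z-scored, inference by 1000-fold pairs bootstrap); and per-trait hierarchical
mixed models

value<sub>ij</sub> = β₀ + **x**<sub>j</sub>ᵀ**β** + b<sub>i</sub> + ε<sub>ij</sub>,  b<sub>i</sub> ~ N(0, σ²<sub>between</sub>), ε<sub>ij</sub> ~ N(0, σ²<sub>within</sub>)

fit by REML, with repeatability ICC = σ²<sub>between</sub> /
(σ²<sub>between</sub> + σ²<sub>within</sub>) and a fly-resampling bootstrap CI.

**Synthetic data.** Two-state correlated random walks in a disk, von
Mises-style heading fixation or optomotor drift, anti-aliased video
rendering with exact ground truth, and cohort tables with fly random
intercepts, context fixed effects, and a `rank_disruption` knob that
replaces a chosen fraction of the between-fly variance with fresh noise.

## Worked example

`examples/03_individuality_statistics.py` generates a 200-fly cohort in six
contexts with true ICC 0.5 and a 0.5 /°C temperature effect, then asks the
individuality questions:

```
r across a 9 C temperature change: 0.477 (p=8.90e-13)
r against a rank-disrupted context: 0.027 (p=0.70)

ridge GLM on |rank change| (z-scored coefficients):
              time:  +0.21  (SE 0.35, p=0.541)
       temperature:  -0.52  (SE 0.40, p=0.194)
            vision:  +0.10  (SE 0.41, p=0.81)
             arena:  +2.27  (SE 0.55, p=4.18e-05)
  behavioral_state:  +0.16  (SE 0.40, p=0.685)

ICC (repeatability) = 0.440, 95% CI [0.362, 0.508]  (generating value 0.5)
temperature fixed effect = 0.499 [0.478, 0.521] per deg C  (generating value 0.5)
```

Reading: the temperature change moves the whole group (fixed effect ≈ 0.5 per
°C) yet the flies' rank order survives it (r ≈ 0.48 ≈ the attenuation-limited
maximum for ICC 0.5), so the ridge GLM assigns rank change to the one
manipulation that actually scrambles individuality (the `arena` switch, which
was generated with full rank disruption). `examples/01…` and `02…` show the
walking and flight trackers recovering rendered ground truth (centroid RMSE
≈ 0.14 px; optomotor rotation recovered at 120.00 °/s).

## Layout

```
src/idiofly/
  simulate.py   synthetic trajectories, headings, cohorts, video rendering
  arena.py      undistortion, background model, ROI detection
  walking.py    centroid tracker, mm conversion, walking filter
  flight.py     two-scale segmentation, heading tracker, unwrapping
  params.py     behavioral parameter suite
  stats.py      correlations, ranks, ridge GLM, mixed models / ICC
  io.py         CSV / frame-stack / legacy .TXT+.DAT readers and writers
  cli.py        thin typer CLI over the above
examples/       one narrative script per capability
docs/methods.md model assumptions, defaults, numerical choices, limitations
```
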