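# Methods

This note documents the models, defaults, and numerical choices behind
`idiofly`, and what the synthetic validation does and does not establish
about real recordings.

## Coordinate and unit conventions

Image coordinates: origin top-left, x right, y down, pixel centres at
integer coordinates. Arena coordinates: origin at the ROI centre, x right,
y **up** (mathematical convention), millimetre units; the conversion negates
image-y. Angles are degrees, counter-clockwise positive, 0° along +x;
headings live in [0, 360°), body axes in [0, 180°). Times are seconds,
positions mm, speeds mm/s, turning rates deg/s. All tabular output is UTF-8
CSV with headers.

## Walking tracker

The background model is the per-pixel maximum of a video's first and last
frame: a dark fly that moved between the two vanishes, leaving the empty
arena. Per frame, |background − frame| is thresholded (default 25 gray
levels, user-adjustable per run) inside each ROI; connected components
smaller than the minimum blob area (default 4 px²) are discarded. One
surviving blob → its binary centroid is stored. Several → the blob whose
centroid is nearest the previous stored position wins; an exact distance tie
falls deterministically to the lowest component label. None → the previous
position is carried with `detected=False`; frames before the first detection
are back-filled with it. The output always has exactly one row per frame.

**Walking filter.** Positions are only advanced when the current sample lies
at least τ = 0.8 mm (inclusive) from the last *updated* position. Anchoring
to the last update rather than the previous raw frame means sub-threshold
drift can still accumulate across frames and eventually trigger an update —
what the filter suppresses is measurement jitter around a stationary fly,
not slow locomotion. The filter is idempotent.

## Flight tracker

Frames are blurred at two Gaussian scales (defaults: strong σ = 8 px, weak
σ = 2 px at a ~60 px body; scale linearly with fly size) and thresholded at
a gray level (default 128) below which pixels count as fly. The strong blur
erases legs and wings, leaving the body; the weak-blur mask minus the body
mask is the appendage mask. The body axis is the orientation of the
second-central-moment ellipse, in [0, 180°). To resolve the 180° ambiguity
the mask is centred on its centroid and rotated so the axis lies on x; the
half-plane with the **smaller** pixel sum holds the head (head + thorax are
narrower than abdomen + folded wings in the rendered silhouette). An exactly
tied split keeps the previous frame's side and flags the frame. Degenerate
(isotropic) masks and fly-not-found frames carry the previous heading,
flagged, never interpolated; a run with more than 50% failed frames is
rejected. A frame counts as not flying when appendage pixels in the lateral
sectors (45–135° off the body axis, either side) exceed 25% of the body
pixel count — the wing criterion is a declared default, since only the
qualitative event (wings become visible when flight stops) is specified by
the assay. Unwrapping maps successive heading differences to the shortest
arc (−180°, 180°] and cumulates them.

## Arena detection and calibration

ROIs (bright arenas on dark surround) are found by local-mean adaptive
thresholding with a neighborhood of 1/8 of the smaller frame dimension
(rounded up to odd) plus an offset of 5% of the frame's dynamic range,
hole-filling, and connected-component area filtering (default: within 4× of
the largest component). The survivor count must equal the expected count
exactly; the error names both numbers. Rows are formed by 1-D clustering of
centroid-y with tolerance of half the median ROI diameter; within a row,
ROIs sort by x. The ordering is a pure function of centroid coordinates.
`mm_per_px` is fitted per ROI from the known physical size: circle diameter
(49 mm array arenas, 120 mm classic platform) or 13.5 mm Y-maze arm length.
Lens distortion is corrected by resampling through the forward Brown–Conrady
model (radial k1–k3, tangential p1–p2) with bilinear interpolation; the
calibration coefficients are accepted as input — estimating them is a
separate, external step.

## Behavioral parameters

- *% time walked*: updated frames after the first / (n − 1) × 100.
- *Walking speed*: mean step length × frame rate over updated frames only,
  so pauses do not dilute it (a whole-recording average is available as an
  option). A fly with no updated frame has a missing speed, never zero.
- *Vector strength*: mean resultant length R of unit vectors; axial data are
  doubled first. Walking "attention" angles are the movement directions of
  updated steps, treated axially because the two stimulus stripes sit 180°
  apart; a positional-bearing variant is exposed but not default.
- *Angular velocity*: mean (signed) or mean-absolute shortest-arc
  difference × rate. For flight, the signed mode is reported as angular
  velocity and the absolute mode as absolute angular velocity.
- *Median heading axial*: headings folded mod 180°, doubled; the circular
  median minimises summed arc distance, with ties among sample minimisers
  resolved to their circular mean; halved back to [0, 180°).
- *Centrophobicity*: fraction of frames beyond 80% of the arena radius. The
  uniform-occupancy baseline is 1 − 0.8² = 0.36 and is *not* subtracted:
  the raw edge fraction is the parameter.
- *Pauses*: maximal non-flying runs of at least 0.2 s (default).
- *Heatmap ceiling*: 95%-quantile of the **nonzero** bin counts, so empty
  bins (and hence arena/frame size) cannot dilute the color scale.
- *Non-movers* (no updated frame, or no flying frame) are excluded from
  cohort tables and reported, not silently dropped.

## Individuality statistics

**Percentile ranks** use average ranks for ties, scaled (rank − 1)/(n − 1)
× 100; the rank-change response is the *absolute* rank difference, since
upward and downward shifts are equally inconsistent.

**Ridge GLM.** Binary predictors code which of {time, temperature, vision,
arena, behavioral state} changed within a context pair. Predictors are
z-scored once on the full data (constant columns dropped with a warning;
the same statistics are reused inside CV folds, matching the stated order:
normalise, then fit). λ is chosen on a 25-point log-spaced grid over
10⁻⁶–10⁶ by seeded 5-fold CV minimising MSE; the final fit uses all rows at
λ*, intercept unpenalised. Inference: 1000 joint (X, y) pairs-bootstrap
resamples refit at λ*; SE = bootstrap SD; two-sided p from the normal tail
of coefficient/SE (with B = 1000 the normal and t references are
indistinguishable; this df choice is the documented default). Resamples
that collapse a predictor to a constant are redrawn, capped at 10×B.

**Mixed model.** Per trait: value ~ intercept + numeric context factors
(day 1–3, temperature °C, stripes 0–2, light 0/1, arena 0/1; factors with
one level, or linearly dependent on those already included, are dropped so
the design has full rank) + fly random intercept, fit by REML. ICC =
σ²_between/(σ²_between + σ²_within). REML optimizers stop slightly off the
zero boundary, so a between-fly variance below 1% of the residual variance
is reported as a singular fit with ICC 0 (flagged, not raised). The ICC CI
resamples flies with replacement (duplicates relabelled as distinct flies,
each keeping its full context set), refits 1000×, and takes the 2.5/97.5
percentiles; more than 10% failed refits flags the CI unreliable.

Raw p-values are reported throughout with no multiplicity correction, and
the normality (Shapiro–Wilk) result accompanies the paired t-test rather
than switching the test.

## Synthetic-data generator

The generator exists to give every downstream stage a ground truth; it is a
declared test fixture, not a model of fly behavior.

- *Walking*: a two-state (walk/pause) Markov chain whose stationary walking
  fraction equals the profile's activity, with mean walking-bout length 2 s;
  while walking, direction evolves as previous + Gaussian noise (sd =
  `turn_noise`) + a fractional pull toward the nearer of the two opposite
  stimulus bearings + a fractional pull outward; step length =
  base_speed × speed_scale / rate; positions reflect at the wall. The axial
  pull makes vector strength respond monotonically to the attraction weight.
- *Flight*: mean-reverting deviation around a preferred heading (reversion
  rate set by the attraction weight), or constant drift in optomotor mode;
  geometric pause bouts hold the heading with `flying=False`.
- *Cohorts*: value = grand mean + fly intercept N(0, σ²_between) + Σ slope ×
  factor code + residual N(0, σ²_within). A context's `rank_disruption` d
  replaces the intercept by √(1−d)·b + √d·fresh, keeping the marginal
  between-fly variance while degrading rank preservation: d = 0 is pure rank
  preservation, d = 1 destroys it.
- *Rendering*: bright anti-aliased arena disks (4× supersampled coverage) on
  dark surround, one dark body ellipse per ROI oriented along the movement
  direction; the tethered close-up renders a tapered body (head end
  narrower, carrying less pixel mass — what the head-assignment rule relies
  on) and, in non-flying frames, two thin translucent wing ellipses swept
  back from the thorax, dark enough to threshold at the weak blur scale but
  washed out by the strong one.

What passing on this fixture shows: the trackers recover sub-pixel centroids
and 360° headings from images with the assumed geometry (dark fly, bright
uniform back-light, one fly per ROI), the parameter definitions behave as
specified, and the statistics recover known variance structure. What it does
not show: robustness to non-uniform illumination, reflections, grooming
postures, flies walking on domes, occlusions, or compression artifacts —
real-data concerns that no synthetic fixture certifies.

## Problem sizes used in validation

The shipped checks use 25 rendered arenas × 60 s at 15 fps for tracker
fidelity, the full 120 s at 90 fps for optomotor recovery, 200 flies × 4
contexts for ICC recovery (estimates averaged over five seeded replicates,
since a single table's sample ICC has sd ≈ 0.045 at that size), and 100
seeded replicates for fixed-effect CI coverage. Bootstrap defaults are
B = 1000 in the API; validation runs use smaller B where only determinism
or CI shape is under test.

## Known limitations

- The legacy paired .TXT/.DAT export is versioned and documented, not
  asserted bit-compatible with the historical analysis software's dialect.
- AVI/MJPEG video I/O requires an imageio codec plugin; the always-available
  interchange formats are multipage TIFF and .npy stacks.
- Y-maze ROIs are handled as circular footprints with arm-length scaling;
  arm-resolved parameters (turn handedness per arm) are not implemented.
- One fly per ROI is assumed throughout; there is no multi-fly identity
  matching.
- The wing-detection criterion and the flight signed/absolute angular
  velocity assignment are declared defaults where the assay specifies only
  qualitative behavior.
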