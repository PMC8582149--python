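# Methods

`atriu` estimates the maximum left-atrial (LA) volume from paired long-axis
cine views with the biplane area-length method and wraps the estimation in an
assisted workflow in which every automatic step can be reviewed and
overridden. This note records the models, the conventions, and the design
choices that were genuinely open.

## The volumetric model

The biplane area-length estimate is

    LAV_max = (8 / 3π) · A_2ch · A_4ch / L        [mm³ → mL by /1000]

where `A_2ch`, `A_4ch` are the LA areas traced on the two-chamber and
four-chamber views at end-systole and `L` is the shorter of the two
longitudinal diameters. The formula is exact when the atrium is an ellipsoid
cut by two orthogonal planes through its long axis and `L` spans the full
long axis; the package's unit tests exploit this (sphere of radius 20 mm →
33.5103 mL, semi-axes (15, 20, 30) mm → 37.699 mL, both to 1e-6 relative).

`LAVI_max` divides by the Mosteller body surface area
`sqrt(height_cm · weight_kg / 3600)`; the literature on LA indexing does not
pin one BSA formula, and Mosteller is the most common and the simplest.

The end-systolic (ES) frame is defined from the mitral valve: each 4ch frame
is classified closed/open and the **last frame of the largest block of
consecutive closed states** is the ES frame. Runs are analyzed linearly; a
`cyclic=True` option merges a run that wraps across the cine boundary
(clinical cines normally start near end-diastole, so the closed block rarely
wraps). Ties between equal-length runs resolve to the earliest run; the tie
rule is arbitrary but must be fixed for reproducibility. The classifier's
probability threshold is fixed at 0.5 (no calibration data to justify
anything else).

## Learned stages

All three learned stages are deliberately desk-scale, deterministic given a
seed, and trainable in about a minute on one CPU from the phantom generator
(20 studies):

* **Valve-state classifier** — a small MLP (64/32 hidden units) on frames
  downsampled to 32×32 with aspect-preserving padding, optimized by SGD with
  momentum 0.9 under cross-entropy loss, with the closed state as the
  positive class. Training frames are additionally replicated with additive
  Gaussian intensity jitter (sd 0.02, two copies); without the jitter a
  classifier trained on clean images is brittle to acquisition noise.
* **LA segmenter** — a per-pixel random forest (30 trees, depth ≤ 14) on
  multiscale intensity/edge/texture features (σ 0.5–4 px) plus normalized
  image coordinates — the classical trainable-segmentation approach. The
  probability map is thresholded at 0.5 and post-processed: keep the largest
  4-connected component, fill enclosed holes (idempotent; post-processing
  can only remove pixels or fill fully enclosed holes). A `context_3d`
  variant appends the mean of the two neighbouring slices as an extra
  feature channel for slice-wise segmentation of axial stacks.
* **Hinge-point localizer** — the same feature stack feeding a random-forest
  regressor of two Gaussian heatmaps (σ = 3 px), one per mitral annular
  hinge point; the sub-pixel peak is the center of mass of the 5×5 window
  around the argmax. Heatmap regression is the natural adaptation of a
  spatial-map architecture to landmark localization, and sub-pixel peak
  extraction avoids the 1 px quantization of a bare argmax. A flat heatmap
  (peak below 0.05) raises "landmark not found" and the pipeline asks for
  manual points.

Landmark pairs are ordered canonically by column (`p_left.col <
p_right.col`); comparison metrics match points by that order. The landmark
distance sum and the annular angle are computed in physical mm coordinates
so anisotropic spacing cannot bias them.

## Geometry conventions

Pixel coordinates are 0-based (row, col) with pixel centers at integer
positions; mm = pixels × per-axis spacing. Lengths are mm, areas mm²,
volumes mL throughout.

* **Diameter construction (default, `centroid` variant).** The ray starts at
  the midpoint of the mitral annular level and passes through the mask
  center of mass; its length is the distance to the farthest mask-boundary
  crossing (the posterior wall), located by 0.1-px-step sampling and
  bisection to 0.01 px. The `perpendicular` variant sweeps base points along
  the annular segment at 0.5-px steps and returns the longest perpendicular
  to the mask side.
* **Continuous boundary for diameters.** A point is inside the mask where
  the bilinearly interpolated binary image is ≥ 0.5, i.e. the region
  extends half a pixel beyond the boundary pixel centers. For a region
  rasterized by the pixel-center-inside rule this level set is an unbiased
  estimator of the underlying continuous boundary; anchoring the boundary at
  pixel centers instead would shorten every diameter by up to one pixel's
  fractional part and bias volumes upward at coarse spacing.
* **Boundary for the Hausdorff metric.** The 8-connected inner boundary
  pixel centers (image border counts as outside). Both masks live on the
  same lattice, so the half-pixel support question cancels; pixel centers
  give bit-reproducible values. Dice of two empty masks is defined as 1.0 so
  stack slices beyond the atrium compare as agreeing.

The 3-D stack volume is the plain slice sum Σ areaᵢ · thickness.

## The phantom

The phantom supplies the ground truth that replaces clinical data: one
analytic ellipsoid with semi-axes (a, b, c); the 2ch view is the (a, c)
plane and the 4ch view the (b, c) plane, sharing the vertical long axis c.
Semi-axes follow a cosine contraction cycle peaking at the ES frame
(default amplitude 0.25, matching a typical LA emptying fraction around
50 % in linear scale). The valve is a bright 2-px line on the annular
plane — a continuous chord when closed, two separated leaflet stubs when
open — and the closed frames form one contiguous block ending at the ES
frame, so the ES selection rule is consistent with the truth by
construction. Intensities are piecewise constant (background 0.2,
myocardial rim 0.45, blood pool 0.9, valve 1.0) plus Gaussian noise
(default sd 0.02).

Defaults: 96×96 px at 1.4 mm spacing, 25 frames per cycle, semi-axes
(20, 24, 32) mm — a typical adult LA at a typical cine resolution. The
training suite draws semi-axes uniformly from (14–26, 16–30, 26–40) mm.

The annular plane sits at 0.985 of the long semi-axis below the center.
Strictly below 1 so that the two hinge points are distinct; close to 1 so
that the longitudinal diameter spans nearly the full long axis, as the
biplane formula assumes. The residual bias is 2/(1+0.985) ≈ +0.76 % of
volume and is part of the phantom's error budget. An optional view-tilt
parameter (default 0°) rotates both imaging planes about the long axis to
probe sensitivity to slice positioning.

What the phantom does **not** emulate: MRI physics (coil shading, banding),
pulmonary veins and the appendage, papillary structures, through-plane
motion, and pathological shape families. Passing the phantom suite therefore
demonstrates that the pipeline's geometry and logic are correct and that the
learned stages can recover known shapes at realistic noise — not that the
desk-scale models generalize to clinical CMR.

## Evaluation components

* **Bland–Altman**: bias = mean difference, limits of agreement = bias ±
  1.96 × sample (n−1) SD. Bounds membership (for the confidence-bound check)
  uses a closed interval.
* **Time model**: per-step expected saving = manual seconds × (p₀ + 0.5 p₁)
  over the score proportions (score 0 = no correction, 1 = minor,
  2 = redo). Per-step values are rounded half-up to 0.1 s before summing —
  the reporting convention of the clinical table this model mirrors, whose
  subtotal (94.1 s) is the sum of the rounded step values — and the reading
  time of the proposals (23.0 s) is subtracted. Percentages are rounded
  half-up to whole percent.
* Defaults: manual times 5 / 80 / 20 s for ES detection, segmentation (both
  views) and landmark placement; 105 s total.

## Pipeline behaviour

When the 2ch and 4ch cines have different frame counts, the 4ch ES index is
transferred by proportional frame position (rounded to the nearest frame)
and the mapping is noted in the audit log. Any stage failure downgrades the
run to "needs manual input" for that stage instead of aborting — the
assisted-workflow philosophy is that humans fix sporadic failures. After any
override all downstream quantities are recomputed, so a corrected mask also
refreshes the diameters and the volume; an overridden stage's contribution
is by construction independent of the loaded models.

## Problem sizes and known limitations

The test and acceptance suites train on 20 noiseless phantom studies and
evaluate on 20 held-out studies at the default noise level; with these
sizes the full suite runs in a few minutes on one CPU. The end-to-end
oracle-annotation check sweeps eight (semi-axes, spacing) pairs covering
semi-axes 10–40 mm and spacings 0.8–2.0 mm, pairing coarse spacing with
larger atria so the shortest semi-axis stays at or above ≈7 px; below that,
the rasterization error of the ground-truth masks themselves (not the
volumetry) dominates and no area measurement from such a mask can stay
within a few percent.

Known limitations: the learned stages are phantom-scale stand-ins for
full-scale encoder-decoder networks and carry no claim of clinical
performance; the diameter's distal endpoint is defined as the farthest
boundary crossing (the proximal end is the annular midpoint by definition,
but the distal convention is this package's choice); and whether the LA
label should include the appendage or pulmonary-vein ostia is a labeling
convention real-data users must fix for themselves.
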