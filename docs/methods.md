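# Methods

This note documents the simulation and analysis model implemented in
`ctvolumetry`: what is emulated, the numerical choices, and what the
synthetic study can and cannot say about real scanners.

## Phantom model

The digital phantom is a rectangular gelatin block (default
15.2 × 15.2 × 40.0 cm, background 37.6 HU) containing PMMA spheres
(118.2 HU) arranged in horizontal layers, one sphere of each diameter
per layer, one layer per replicate.  The default diameter series is
the inch-fraction ladder 1/16″ … 1″ (1.5875–25.4 mm): precision-molded
spheres are sold in inch fractions, and the commonly quoted metric
labels (1.6, 3.2, 6.4, 25.4 mm) are rounded versions of exactly these
values — the quoted true volumes (16.8, 134, 8580 mm³) back-calculate
to the inch fractions, not to the rounded labels.

In-plane positions are drawn by seeded rejection sampling with a 5 mm
surface-to-surface clearance and a 3 mm wall margin; each layer's
z-position receives a seeded jitter of up to ±3 mm so that every
replicate sits at a different phase relative to the slice grid.  This
jitter is the model's source of replicate-to-replicate variability in
the noiseless limit, standing in for the arbitrary placement of real
spheres in poured gelatin.  Layer pitch (80 mm for 5 layers in 40 cm)
far exceeds the largest sphere, so cross-layer interactions cannot
occur.  The degenerate one-sphere/one-replicate request bypasses
sampling and centers the sphere.

## Voxelization and the partial-volume effect

A voxel's HU is the volume-fraction-weighted mean of the two
materials: `bg + occupancy · (sphere − bg)`.  Occupancy is resolved
analytically for voxels provably inside or outside a sphere (center
distance vs radius ± half the voxel diagonal) and by counting on a
`supersample`³ subgrid (default 8, i.e. 512 points) for the boundary
shell, so cost scales with surface area.  At 0.2 mm isotropic voxels
and supersample 8, the occupancy-integrated volume of a 25.4 mm sphere
agrees with (4/3)πr³ to better than 1%; at the native study
resolution, supersample 8 keeps occupancy quantization (1/512 per
voxel) far below the threshold-placement effects being studied.
Voxels span half-open boxes; indices are 0-based `[z, y, x]`; sphere
centers live in continuous mm with the container corner at the world
origin.  When a reconstruction matrix is given, the xy grid is the
matrix-sized field of view centered on the container, as a scanner
would reconstruct it.

## Kernel emulation

A reconstruction kernel is modeled as an in-plane Gaussian PSF of
width `psf_sigma_xy` plus additive zero-mean Gaussian noise of
per-voxel standard deviation `noise_sigma`.  The noise field is white
noise filtered by the same in-plane PSF and rescaled to `noise_sigma`
(the exact discrete variance-retention factor of the filter is
computed from the 1-D kernel): a reconstruction kernel shapes noise as
well as signal, and voxel-independent noise would interact with the
connectedness filter to erode object surfaces in a way no real
reconstruction shows.  Noise is independent across slices.  Defaults
(configurable): PSF 0.8 / 0.5 / 0.3 mm and noise 4 / 10 / 8 HU for
standard / bone / lung, giving the clinically familiar ordering —
the standard kernel smoothest and quietest, lung sharpest (most
accurate) with a noisy error profile, bone in between and noisiest.
No frequency-domain filter shapes, beam hardening, dose dependence or
helical artifacts are modeled.

## Thick-slice synthesis

Thicker slices are weighted means of contiguous thin slices: output
slice *k* covers the thin-slice interval
`[phase_skip + k·s, phase_skip + (k+1)·s)` with fractional end slices
weighted by their coverage (`s` = slices per thick slice, possibly
fractional, e.g. 9.625 thin slices of ~0.52 mm spacing per 5 mm
slice).  The main experiment uses exact integer factors 2/4/8 over
0.625 mm native slices with zero phase.  `phase_shift_search` scans
candidate skips (default 0–9) and minimizes the mean absolute HU
difference against a reference thick stack; the mean *absolute*
difference is used because a signed mean is ≈0 for any alignment and
carries no information.  Ties break toward the smaller skip.  On
noiseless stacks the search recovers a planted phase with metric
exactly zero.

## Segmentation

Foreground is HU ≥ threshold (inclusive — fixed so results are
bit-reproducible; either convention is defensible).  Components are
labeled with 26-adjacency and renumbered by first voxel in (z, y, x)
raster order so labelings are deterministic.  Two filters follow:

* **Connectedness**: voxels with fewer than 3 foreground neighbors in
  the 26-neighborhood are removed, iterated to a fixed point (removing
  a voxel can expose new violators), then the mask is relabeled.  The
  26-neighborhood is used for counting because the filter's job is to
  delete isolated noise specks and one-voxel strands while leaving
  compact object surfaces intact; counting face-neighbors only turns
  the rule into a surface-erosion operator that biases every volume
  measurement by 1–5% depending on grid resolution.
* **Minimum volume**: components smaller than 10% of the smallest
  analyzed sphere's true volume (1.68 mm³ for the 3.175 mm sphere),
  recomputed from the configured diameter list, are deleted and labels
  compacted.

The filter is idempotent and never adds voxels.

## Threshold calibration

The threshold sweep segments a calibration volume at each threshold
(default 90/100/110 HU), matches components to spheres, averages
percent error within each size class, and reduces to min/median/max
across classes.  An ordinary least-squares line through (threshold,
median error) gives the zero-error crossing as the case optimum; the
global threshold is the rounded mean over the calibration cases
(default trio: smoothest, intermediate and noisiest condition).  The
shipped default pipeline applies the fixed calibrated value of 93 HU;
`threshold: calibrate` in the config runs the procedure instead.
Sweep points that detect nothing are flagged `empty`, and points whose
largest component exceeds twice the largest true sphere volume
(threshold at or below background, merging everything) are flagged
`degenerate`; both are excluded from the fit rather than raised,
since a sweep is exploratory by nature.

## Measurement and matching

Component volume is exactly `N_V · l · w · t`; centroids are mean
voxel centers.  A component is attributed to the sphere with the
nearest center if the distance is within that sphere's radius plus one
voxel diagonal (the gate must scale with resolution; blur shifts
centroids by far less than a voxel).  Distance ties go to the lower
sphere id.  If several components fall in one gate, the largest is the
measurement and the rest are counted as fragments.  Spheres with no
gated component are non-detections and are excluded from all accuracy
and precision statistics (their slots still appear in the measurement
table).  The smallest size class (1.6 mm) is generated but excluded
from analysis by default — at every tested resolution its segmentation
is dominated by quantization and detection failure.

## Statistics

* COV uses the sample (n−1) standard deviation over the mean — five
  replicates are a sample, not a population.
* The 95% CI is t-based (`mean ± t₀.₉₇₅,ₙ₋₁·SE`), appropriate at n=5.
* The origin-forced slope is `Σ(V_true·V_CT)/ΣV_true²` with the
  uncentered r², the standard convention for regression through the
  origin.
* ANOVA is classical one-way, fitted one factor at a time (sphere
  size, slice thickness, FOV, kernel) on detected percent errors;
  pairwise two-sample t-tests are Bonferroni-multiplied and capped at
  1.
* Tolerance lookup curves use the mean over replicates of |percent
  error| per diameter, linearly interpolated; the reported minimum
  diameter is the smallest d whose interpolated error stays within
  tolerance for **all** larger tested diameters, with sentinels when
  the largest diameter fails ("> max tested") or the smallest passes
  ("< min tested").

`VolumetryAccuracyModel` wraps the tidy measurement table;
`fit()` returns a results object carrying these tables, a text
`summary()`, and matplotlib views (percent error vs diameter per
thickness; slope vs thickness per kernel/FOV).

## Problem sizes and determinism

The full default grid is 3 FOV × 3 kernels × 4 thicknesses = 36
conditions, 55 spheres each, 50 analyzed per condition = 1800
measurement slots.  The packaged study runs (tests and
`scripts/acceptance.py`) use a 256 reconstruction matrix — half the
clinical 512 — which preserves every qualitative effect while keeping
a full run to a few minutes on one CPU; pixel sizes then span
0.78–1.56 mm instead of 0.39–0.78 mm.  Volumes are cropped to the
container footprint before segmentation, exactly as a workstation
would crop surrounding air.  All randomness (layout, z-phase, noise)
derives from one config seed via independent streams; identical seeds
give byte-identical output tables.

## What the synthetic study does and does not show

The emulation reproduces the physics that drives threshold volumetry:
partial-volume mixing, kernel blur/noise trade-offs, slice-averaging,
and threshold placement.  On the reduced default run it reproduces the
qualitative findings — universal underestimation (all 36 slopes < 1),
accuracy falling with slice thickness and rising with diameter, FOV
statistically insignificant while kernel and thickness are strongly
significant, and a ~34% detection rate for the 3.2 mm sphere.  It does
not model scanner-specific PSFs, dose-dependent or spatially varying
noise, gelatin inhomogeneity, container walls, or helical acquisition;
absolute error magnitudes therefore characterize this simulator, not
any particular scanner, and the numeric agreement of the per-thickness
underestimation with published phantom values should be read as
consistency, not calibration.  Two known edge behaviors at the reduced
matrix: the bone kernel's high noise makes the 0.625→1.25 mm slope
step nearly flat (its sign can fluctuate with the noise realization),
and at the coarsest FOV the 3.2 mm sphere's discretization bias can
exceed replicate standard errors, weakening FOV-insensitivity at that
single size.
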