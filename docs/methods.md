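# Methods

`phasecell` segments and tracks a single cell in cropped phase-contrast
time-lapse recordings.  Phase-contrast optics give label-free contrast to
thin structures such as pseudopodia, but surround the dark cell body with a
bright artifactual rim (the halo) that defeats edge- and region-based
segmentation.  The pipeline runs four stages per frame: mixed
Poisson–Gaussian denoising, halo removal by background division,
localized Chan–Vese active-contour segmentation, and centroid tracking.

## Noise model and estimation

Frame intensities are normalized to [0, 1].  The sensor model is

    y = x + n,   Var(y | x) = alpha * x + sigma^2

with `alpha` the Poisson (shot-noise) gain and `sigma` the Gaussian read
noise.  `estimate_noise` cuts a frame into non-overlapping 16 px patches,
discards patches touching the intensity range limits (clipped pixels
deflate the sample variance), keeps the most homogeneous half by gradient
energy, and fits `variance = alpha * mean + sigma^2`.

Two estimator details matter in practice:

- The rank-based "keep the lowest-energy half" screen truncates the
  patch-variance distribution of the marginally-included intensity level
  and would bias the fitted slope.  The rank screen therefore only
  bootstraps an initial line; patches are re-admitted wherever their
  gradient energy is consistent with pure noise at their predicted level
  (`energy <= 5 * predicted_variance`, i.e. 25% head-room over the
  flat-patch expectation of `4 * variance`), and the final precision-
  weighted fit (weights ~ 1/variance^2, the precision of a sample
  variance) runs on that unbiased set with a relative-residual outlier
  trim.
- A single flat level cannot identify `alpha` and `sigma` separately, so
  when the kept patches span less than 0.05 in mean intensity the variance
  is attributed entirely to the Gaussian term.

`estimate_noise_stack` pools all frames' patch statistics into one fit;
this is the multi-frame average of the per-frame procedure with far better
conditioning of the small Gaussian intercept.

`phantom.flat_calibration_stack` provides the matching calibration target:
a step wedge of flat bands.  Band edges align with the 16 px patch grid
(patches must not straddle steps), the darkest bands get double width
(they anchor the Gaussian floor, as in photon-transfer-curve practice),
the lowest level is 0.1 (further down, clipping at 0 corrupts the
variance), and the brightest band (0.85) is close enough to saturation
that the estimator's clipping screen is exercised.

## Variance stabilization and BM3D

For `alpha > 0` the generalized Anscombe transform

    f(y) = (2/alpha) * sqrt(alpha*y + (3/8)*alpha^2 + sigma^2)

maps the mixed noise to approximately unit-variance Gaussian; the
algebraic inverse is used on the way back (an exact-unbiased inverse is a
non-goal at these noise levels).  BM3D then runs on the transformed frame
affinely rescaled to [0, 1] with `sigma = 1/(max - min)`, so the matching
thresholds below keep their [0, 1]-scale meaning; pure-Gaussian frames
(`alpha = 0`) are filtered directly with the estimated sigma.

BM3D parameters (standard reference values): 8x8 blocks, step 3, 39 px
search window, groups capped at 16 blocks, tau_match 3000/255^2 (hard
threshold stage, distances on 2-D DCT coefficients hard-thresholded at
`2.0 * sigma`) and 400/255^2 (Wiener stage, plain distances on the basic
estimate), 3-D threshold `2.7 * sigma` with the DC coefficient exempt so
the group mean survives.  The separable 3-D transform is an orthonormal
2-D DCT-II per block followed by an orthonormal Haar transform across the
stack; groups are truncated to the largest power of two at or below the
match count so the Haar transform is always exact.  Hard-threshold groups
aggregate with weights `1/(sigma^2 * N_retained)` (1 when nothing
survives), Wiener groups with `1/(sigma^2 * ||W||^2)`; degenerate weights
are capped at 1e8, which preserves ordering while avoiding division by
zero.  An extra row/column of reference blocks is forced at the right and
bottom edges so every pixel is covered and aggregation is a true convex
combination.  Frames are denoised independently; no temporal grouping.

With `sigma = 0` both stages reduce to the identity (zero thresholds, all
shrinkage coefficients at 1), which is tested.

## Halo removal

The frame is divided into 16 px tiles (edge tiles truncated), each
summarized by its intensity mean and standard deviation, z-scored across
tiles.  K-means with k = 2 (k-means++, 10 restarts; features fitted in
lexicographic order so labels do not depend on tile enumeration) splits
homogeneous background tiles from tiles containing cell or halo signal.
The background cluster is the one with the lower mean raw standard
deviation — background tiles are nearly identical in distribution — with
ties going to the larger cluster, then to the cluster containing the
flattest tile.

The background image B is, by default, the scalar mean intensity over all
pixels of background tiles ("scalar" mode).  A "tilewise" mode assembles B
from per-tile means with nearest-background filling and Gaussian smoothing
for shaded fields; it exists because a spatially varying background is
common in practice, but the scalar reading is the default.  The corrected
image is `R = I/B` with every ratio at or above 1 — background and halo
alike — clamped to exactly 1, and a floor of 1e-6 keeping the output in
(0, 1].  Cell pixels, darker than the background, keep ratios below 1, so
the corrected frame is close to a two-level image: an ideal input for a
region-based contour.

## Localized Chan–Vese segmentation

The contour is the zero level of phi (negative inside).  The energy
balances a length term `mu`, an area term `nu`, and fit terms
`lambda1 * (u0 - C1)^2` inside / `lambda2 * (u0 - C2)^2` outside, where in
localized mode C1 and C2 are per-pixel means over the strict Euclidean
ball of radius `r` (computed by FFT convolution with the disc kernel;
neighborhoods clip at the image border).  Localized mode is the default;
global means are kept for baselines and reduce to the localized ones when
`r` exceeds the image diagonal.

Defaults: `mu = 0.1`, `nu = 0`, `lambda1 = lambda2 = 1`, `r = 9` px,
`epsilon = 1.5` px for the regularized Heaviside/Dirac, `dt = 0.5`,
`max_iter = 500`, `tol = 1e-4`.  The length weight is deliberately small:
on the ratio image the fit contrast across a pseudopodium is about
`(0.6 - 1)^2 ≈ 0.16` per pixel while each pixel of a 5 px-wide protrusion
costs roughly `2 * mu` of perimeter; `mu = 0.2` visibly rounds off
pseudopod tips and biases the centroid, `mu = 0.1` keeps them while still
suppressing noise islands.

Numerics.  The update is

    phi <- phi + dt * (delta_eps(phi)/delta_eps(0)) * F / max|F|

restricted to the narrow band |phi| <= 6 px (full-grid updates behind a
flag for oracle tests), with `F = mu*kappa + nu + lambda1*(u0-C1)^2 -
lambda2*(u0-C2)^2` and curvature by central differences (|grad phi|
floored at 1e-8).  Both normalizations make `dt` a front speed in pixels
per step; without them, pixels one ring ahead of the zero crossing receive
heavily suppressed updates and the front advances in bursts.  phi is
rebuilt as a signed distance (Euclidean distance transform, half-pixel
centered) every 25 iterations.  The energy trace uses the sharp region
indicator and an edge-count perimeter, which makes it invariant under
reinitialization.  Note that with `mu > 0` the *discrete* energy is not
monotone under single-pixel moves (flipping one pixel always pays about
two edges of perimeter before its neighbors follow), so strict descent is
only guaranteed — and only asserted — for the fit terms (`mu = nu = 0`);
with the default parameters the trace still descends to within a fraction
of a percent on clean fixtures.

Convergence is declared when the fraction of pixels whose phi sign changed
over the last `reinit_every + 10` iterations falls below `tol`; a window
spanning a full reinitialization cycle avoids pause-triggering on the
bursty discrete front motion.  The final mask is the connected component
of {phi < 0} containing the initialization center, holes filled, boundary
traced counter-clockwise.

Initialization detects the darkest circular object: a circular Hough
transform over the expected radius range on strong Sobel edges, the top
peaks ranked by interior darkness, and the winning disc shrunk by 20% so
the contour starts inside the cell.  If no circle is found the fallback is
a disc of the mean expected radius at the intensity-weighted darkness
centroid.  In the multi-frame pipeline only the first frame is initialized
this way; subsequent frames warm-start from the previous mask (cells move
about a pixel per 2-minute frame), with automatic re-detection if the
contour collapses.

## Tracking and metrics

The tracked point is the unweighted mean pixel coordinate of the filled
mask, at sub-pixel precision; times default to 120 s per frame.  Two
trajectories over the same frames are compared by the per-frame Euclidean
distance, summarized by its mean, maximum, and sample variance (n-1
denominator; the variance is in px^2 even though the distances are px).
Per-axis signed differences are reported alongside for transparency, and
both trajectories can optionally be shifted to their starting points
before comparison.  Trajectory CSVs store `x = column`, `y = row` to match
image-viewer conventions.

## Synthetic phantoms

`generate_phantom` renders what the pipeline is meant to see: a dark
elliptical body (axis ratio 0.85) with tapered pseudopodia at seeded
random angles, at intensity `cell_level = 0.33` on a
`background_level = 0.55` field, ringed by a halo band of width 3 px at
`background * (1 + halo_gain)`, moving by a reflected random walk
(default 1 px/frame per axis) that keeps the cell inside the frame, under
the mixed noise law, clipped to [0, 1] like an 8-bit sensor.  The cell
edge is anti-aliased by 4x4 supersampled coverage blending toward the
background, while the halo band is a hard morphological dilation ring of
pure halo level; this guarantees, for every valid parameter set, that
every truth-rim pixel is strictly brighter and every truth-mask pixel
strictly darker than the background.  Shape is rigid over time (no
protrusion dynamics), the halo has uniform gain, and no phase-contrast
point-spread or shading is modeled — so passing tests demonstrate correct
mechanics and the value of halo removal, not performance on real optics.

Halo-suppression checks run on noise-free phantoms: "rim pixels equal
exactly 1 after correction" is only well-posed without noise.

## Problem sizes used in tests and the acceptance script

Unit fixtures are 12–64 px; denoising benchmarks use a single 128x128
phantom at sigma = 0.08; the pipeline comparison uses 96x96 phantoms
(cell radius ~13 px, two pseudopodia, halo gain 0.3, sigma = 0.05) — 5
phantoms x 10 frames in the test suite and 3 x 8 in the acceptance
script.  On one CPU the full suite runs in a few minutes, dominated by
the pipeline comparison.

## Known limitations

- Single cell per field; multi-cell scenes must be cropped upstream.
- The localized contour needs its initialization within the localization
  radius of the true boundary (guaranteed here by the Hough step); discs
  far inside a large uniform region do not move.
- The algebraic Anscombe inverse is biased at very low counts.
- The tilewise background mode is smoothed per tile and will not track
  shading varying faster than the tile size.
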