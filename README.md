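# phasecell

Single-cell segmentation and tracking for phase-contrast time-lapse
microscopy.

Phase-contrast imaging is the workhorse for label-free cell-migration
studies: it reveals thin, transparent structures such as pseudopodia that
drive locomotion.  The same optics, however, wrap every dark cell body in
a bright halo rim that confuses edge- and region-based segmentation, so
naive active contours mis-place the boundary and corrupt downstream
motility statistics.  `phasecell` implements a pipeline that removes the
obstacles before contouring:

1. **Denoising** — the mixed sensor noise `Var(y|x) = alpha*x + sigma^2`
   (Poisson shot noise plus Gaussian read noise) is estimated from
   homogeneous image patches, stabilized with the generalized Anscombe
   transform `f(y) = (2/alpha) * sqrt(alpha*y + 3/8*alpha^2 + sigma^2)`,
   and filtered with two-stage BM3D: similar 8x8 blocks are grouped into
   3-D stacks, jointly hard-thresholded in a DCT+Haar transform domain to
   form a basic estimate, then Wiener-shrunk using that estimate, with
   overlapping blocks aggregated by inverse-variance weights.
2. **Halo removal** — frames are cut into tiles whose (mean, std)
   statistics are split by k = 2 K-means into homogeneous background
   tiles and signal tiles; the mean intensity of the background tiles
   defines the background image `B`, and the ratio `I/B` is clamped at 1
   so halo and background collapse to a flat field while the darker cell
   keeps its contrast.
3. **Segmentation** — a localized Chan–Vese level set minimizes
   `mu*Length + nu*Area + lambda1*∫_in (u0-C1)^2 + lambda2*∫_out (u0-C2)^2`
   with the region means C1, C2 taken per pixel within a radius-r ball, so
   the contour follows thin pseudopodia; it is initialized by circular
   Hough detection of the darkest round object.
4. **Tracking** — the per-frame mass center of the mask forms the
   trajectory; trajectories are compared by the per-time-step Euclidean
   distance (mean, max, sample variance).

A synthetic phantom generator (dark elliptical body, tapered pseudopodia,
bright halo rim, seeded random-walk motion, the exact mixed noise law)
provides ground-truth masks and centroids, so every stage is testable
without external recordings.

## Worked example

```python
import numpy as np
from phasecell import (PhantomSpec, generate_phantom, estimate_noise,
                       process_stack, dice_coefficient, Trajectory,
                       compare_trajectories)

spec = PhantomSpec(frame_shape=(96, 96), n_frames=6, cell_radius=13.0,
                   pseudopod_length=10.0, halo_gain=0.3, noise_sigma=0.05,
                   seed=3)
phantom = generate_phantom(spec)

params = estimate_noise(phantom.stack[0])
print(f"estimated noise: alpha={params.alpha:.4f} sigma={params.sigma:.4f}")

result = process_stack(phantom.stack, init_radius_range=(6, 26))
dice = [dice_coefficient(m, t)
        for m, t in zip(result.masks, phantom.truth_masks)]
print(f"per-frame Dice vs truth: {np.round(dice, 3)}")

truth = Trajectory(np.arange(6), np.arange(6) * 120.0,
                   phantom.truth_centroids[:, 0], phantom.truth_centroids[:, 1])
cmp_ = compare_trajectories(truth, result.trajectory)
print(f"centroid error: mean={cmp_.average:.3f} px  max={cmp_.max_diff:.3f} px  "
      f"variance={cmp_.variance:.4f} px^2")
```

Output:

```
estimated noise: alpha=0.0000 sigma=0.0490
per-frame Dice vs truth: [0.964 0.968 0.969 0.97  0.958 0.963]
centroid error: mean=0.224 px  max=0.387 px  variance=0.0148 px^2
```

The recovered sigma matches the 0.05 that was injected (the phantom has no
Poisson component, and alpha is correctly estimated as 0).  Dice ≈ 0.96
against the ground-truth masks means the contour recovers the cell body
*and* its pseudopodia; the resulting trajectory tracks the true mass
center to about a quarter pixel per frame.  Running the same stack with
`halo_correction=False` (the classic active-contour-only baseline)
roughly triples the centroid error — the halo, not the noise, is the
dominant obstacle.

## Command line

```bash
phasecell simulate --out phantom_dir --frames 10 --seed 1
phasecell run --input phantom_dir/stack.tif --out results_dir
phasecell evaluate --ref manual.csv --test results_dir/trajectory.csv --out metrics.json
```

Subcommands `denoise`, `dehalo`, `segment`, and `track` expose the
individual stages; `run` accepts a YAML config whose sections mirror the
library modules, with CLI flags taking precedence.

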