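"""Synthetic phase-contrast phantoms with ground truth.

A phantom emulates a cropped single-cell phase-contrast field: a dark
elliptical cell body with tapered pseudopodia, a bright halo rim hugging the
boundary (the phase-ring artifact), smooth seeded random-walk motion, and
mixed Poisson-Gaussian noise with a known law
``Var(y | clean) = alpha * clean + sigma**2``.

Every frame comes with its ground-truth cell mask, halo-rim mask, and
sub-pixel centroid, so each downstream stage (denoising, halo removal,
segmentation, tracking) can be scored without external data.  The generator
does not model phase-contrast optics (no point-spread or phase-ring
simulation) - the halo is a geometric bright band.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .denoise import NoiseParams

__all__ = ["PhantomSpec", "PhantomOutput", "generate_phantom", "flat_calibration_stack", "save_phantom"]

_SUPERSAMPLE = 4  # sub-pixel coverage sampling per axis


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity, motion and noise of a synthetic cell recording.

    Intensities are on the [0, 1] scale; the halo rim renders at
    ``background_level * (1 + halo_gain)`` (clipped to 1).  The same spec and
    seed always produce a bit-identical stack.
    """

    frame_shape: tuple[int, int] = (128, 128)
    n_frames: int = 10
    cell_center0: tuple[float, float] | None = None  # defaults to frame center
    cell_radius: float = 18.0
    n_pseudopodia: int = 2
    pseudopod_length: float = 14.0
    pseudopod_width: float = 5.0
    background_level: float = 0.55
    cell_level: float = 0.33
    halo_gain: float = 0.3
    halo_width: int = 3
    motion_step_std: float = 1.0
    noise_alpha: float = 0.0
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cell_level < self.background_level < 1):
            raise ValueError("need 0 < cell_level < background_level < 1")
        if self.halo_gain <= 0:
            raise ValueError("halo_gain must be > 0")
        if self.noise_alpha < 0 or self.noise_sigma < 0:
            raise ValueError("noise parameters must be non-negative")
        if min(self.frame_shape) < 64:
            raise ValueError("frame_shape must be at least 64 x 64")

    @property
    def halo_level(self) -> float:
        return min(self.background_level * (1.0 + self.halo_gain), 1.0)

    @property
    def extent(self) -> float:
        """Maximal distance from the cell center to any rendered cell pixel."""
        return self.cell_radius + self.pseudopod_length


@dataclass
class PhantomOutput:
    """Generated stack plus the ground truth used to score the pipeline."""

    stack: np.ndarray          # (T, H, W) noisy frames in [0, 1]
    clean_stack: np.ndarray    # (T, H, W) noise-free frames
    truth_masks: np.ndarray    # (T, H, W) bool, cell incl. pseudopodia
    truth_halo_masks: np.ndarray  # (T, H, W) bool, pure halo-rim pixels
    truth_centroids: np.ndarray   # (T, 2) sub-pixel (row, col)
    noise_params: NoiseParams
    spec: PhantomSpec


def _reflect(value: float, lo: float, hi: float) -> float:
    """Fold a coordinate into [lo, hi] by mirror reflection."""
    span = hi - lo
    if span <= 0:
        return lo
    v = (value - lo) % (2 * span)
    return lo + (span - abs(v - span))


def _coverage(
    spec: PhantomSpec,
    center: tuple[float, float],
    body_angle: float,
    pod_angles: np.ndarray,
) -> np.ndarray:
    """Fraction of each pixel covered by the cell, via supersampling."""
    h, w = spec.frame_shape
    s = _SUPERSAMPLE
    ys = (np.arange(h * s) + 0.5) / s - 0.5 - center[0]
    xs = (np.arange(w * s) + 0.5) / s - 0.5 - center[1]
    dy = ys[:, None]
    dx = xs[None, :]

    a = spec.cell_radius
    b = 0.85 * spec.cell_radius
    u = dy * np.cos(body_angle) + dx * np.sin(body_angle)
    v = -dy * np.sin(body_angle) + dx * np.cos(body_angle)
    shape = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    length = spec.cell_radius + spec.pseudopod_length
    for ang in pod_angles:
        pu = dy * np.cos(ang) + dx * np.sin(ang)
        pv = -dy * np.sin(ang) + dx * np.cos(ang)
        half = 0.5 * spec.pseudopod_width * (1.0 - 0.6 * pu / length)
        shape |= (pu >= 0) & (pu <= length) & (np.abs(pv) <= half)

    return shape.reshape(h, s, w, s).mean(axis=(1, 3))


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Render a seeded phantom stack with ground truth.

    The cell translates by a reflected random walk (per-axis step std
    ``motion_step_std``) that keeps body, pseudopodia and halo fully inside
    the frame.  The cell edge is anti-aliased (partial-volume coverage blend
    against the background), while the halo band is a hard morphological
    dilation ring at the pure halo level - so every truth-rim pixel is
    strictly brighter than the background and every truth-mask pixel
    strictly darker.
    """
    margin = spec.extent + spec.halo_width + 2.0
    h, w = spec.frame_shape
    if 2 * margin + 4 > min(h, w):
        raise ValueError(
            "cell + pseudopodia + halo do not fit in the frame; "
            "reduce cell_radius/pseudopod_length or enlarge frame_shape"
        )
    rng = np.random.default_rng(spec.seed)
    body_angle = rng.uniform(0.0, 2.0 * np.pi)
    pod_angles = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_pseudopodia)

    center0 = spec.cell_center0 or ((h - 1) / 2.0, (w - 1) / 2.0)
    centers = [
        (
            _reflect(center0[0], margin, h - 1 - margin),
            _reflect(center0[1], margin, w - 1 - margin),
        )
    ]
    steps = rng.normal(0.0, spec.motion_step_std, size=(spec.n_frames - 1, 2))
    for t in range(spec.n_frames - 1):
        cy = _reflect(centers[-1][0] + steps[t, 0], margin, h - 1 - margin)
        cx = _reflect(centers[-1][1] + steps[t, 1], margin, w - 1 - margin)
        centers.append((cy, cx))

    footprint = disk(spec.halo_width)
    clean = np.empty((spec.n_frames, h, w))
    masks = np.empty((spec.n_frames, h, w), dtype=bool)
    halos = np.empty((spec.n_frames, h, w), dtype=bool)
    centroids = np.empty((spec.n_frames, 2))
    for t, center in enumerate(centers):
        cov = _coverage(spec, center, body_angle, pod_angles)
        mask = cov >= 0.5
        halo = ndimage.binary_dilation(mask, structure=footprint) & ~mask
        frame = spec.cell_level * cov + spec.background_level * (1.0 - cov)
        frame[halo] = spec.halo_level
        clean[t] = np.clip(frame, 0.0, 1.0)
        masks[t] = mask
        halos[t] = halo
        centroids[t] = np.argwhere(mask).mean(axis=0)

    noisy = clean.copy()
    if spec.noise_alpha > 0:
        noisy = spec.noise_alpha * rng.poisson(clean / spec.noise_alpha).astype(float)
    if spec.noise_sigma > 0:
        noisy = noisy + rng.normal(0.0, spec.noise_sigma, size=noisy.shape)
    if spec.noise_alpha > 0 or spec.noise_sigma > 0:
        noisy = np.clip(noisy, 0.0, 1.0)

    return PhantomOutput(
        stack=noisy,
        clean_stack=clean,
        truth_masks=masks,
        truth_halo_masks=halos,
        truth_centroids=centroids,
        noise_params=NoiseParams(spec.noise_alpha, spec.noise_sigma),
        spec=spec,
    )


def flat_calibration_stack(
    shape: tuple[int, int] = (256, 160),
    n_frames: int = 10,
    levels: tuple[float, ...] = (0.1, 0.1, 0.16, 0.16, 0.22, 0.3, 0.4, 0.55, 0.7, 0.85),
    alpha: float = 0.0,
    sigma: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Step wedge of flat constant-intensity bands under the mixed noise law.

    Vertical bands at the given levels provide flat patches at several means,
    which is what identifies alpha and sigma separately in a
    ``variance = alpha * mean + sigma**2`` fit.  Returns (noisy, clean).
    """
    h, w = shape
    clean_frame = np.empty((h, w))
    edges = np.linspace(0, w, len(levels) + 1).astype(int)
    for lev, lo, hi in zip(levels, edges[:-1], edges[1:]):
        clean_frame[:, lo:hi] = lev
    clean = np.broadcast_to(clean_frame, (n_frames, h, w)).copy()
    rng = np.random.default_rng(seed)
    noisy = clean.copy()
    if alpha > 0:
        noisy = alpha * rng.poisson(clean / alpha).astype(float)
    if sigma > 0:
        noisy = noisy + rng.normal(0.0, sigma, size=noisy.shape)
    return np.clip(noisy, 0.0, 1.0), clean


def save_phantom(output: PhantomOutput, out_dir: str | Path) -> None:
    """Write the phantom as TIFF stack, per-frame PNG masks, a centroid CSV
    and a JSON sidecar with the spec and applied noise parameters."""
    import imageio.v3 as iio
    import pandas as pd
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        out / "stack.tif",
        (output.stack * 255).round().astype(np.uint8),
        photometric="minisblack",
    )
    tifffile.imwrite(
        out / "clean.tif",
        (output.clean_stack * 255).round().astype(np.uint8),
        photometric="minisblack",
    )
    for t, mask in enumerate(output.truth_masks):
        iio.imwrite(out / f"mask_{t:04d}.png", (mask * 255).astype(np.uint8))
    pd.DataFrame(
        {
            "frame": np.arange(len(output.truth_centroids)),
            "row": output.truth_centroids[:, 0],
            "col": output.truth_centroids[:, 1],
        }
    ).to_csv(out / "truth_centroids.csv", index=False)
    sidecar = {
        "spec": asdict(output.spec),
        "noise_params": {"alpha": output.noise_params.alpha, "sigma": output.noise_params.sigma},
    }
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))
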