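"""Image-stack reading and writing.

Time-lapse input comes as a multi-page TIFF or a lexicographically ordered
PNG/TIFF sequence (8- or 16-bit grayscale); frames are normalized to [0, 1]
floats.  RGB frames are converted to luma with a warning.
"""

from __future__ import annotations

import glob
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .track import DEFAULT_FRAME_INTERVAL_S

__all__ = ["ImageStack", "read_stack", "write_stack", "write_masks", "crop_stack"]


@dataclass
class ImageStack:
    """Ordered grayscale frames in [0, 1] with uniform shape."""

    frames: np.ndarray  # (T, H, W) float
    bit_depth_source: int
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("stack must hold at least one 2-D frame")
        if self.frames.min() < 0 or self.frames.max() > 1:
            raise ValueError("frame intensities must lie in [0, 1]")

    def __len__(self) -> int:
        return self.frames.shape[0]


def _to_gray_float(frame: np.ndarray, origin: str) -> tuple[np.ndarray, int]:
    if frame.ndim == 3:
        warnings.warn(f"{origin}: RGB input converted to luma")
        frame = (
            0.299 * frame[..., 0] + 0.587 * frame[..., 1] + 0.114 * frame[..., 2]
        ).astype(frame.dtype if np.issubdtype(frame.dtype, np.floating) else np.float64)
    if frame.dtype == np.uint8:
        return frame.astype(float) / 255.0, 8
    if frame.dtype == np.uint16:
        return frame.astype(float) / 65535.0, 16
    arr = np.asarray(frame, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        # integer-valued float exports: infer the source depth
        depth = 65535.0 if arr.max() > 255 else 255.0
        arr = arr / depth
        return arr, int(np.log2(depth + 1))
    return arr, 8


def read_stack(
    path_or_pattern: str | Path,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> ImageStack:
    """Load a multi-page TIFF or an ordered image sequence as an ImageStack."""
    path = str(path_or_pattern)
    files: list[str]
    if any(ch in path for ch in "*?[") :
        files = sorted(glob.glob(path))
        if not files:
            raise FileNotFoundError(f"no files match pattern {path!r}")
    elif Path(path).is_dir():
        files = sorted(
            str(p) for p in Path(path).iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF files in directory {path!r}")
    else:
        if not Path(path).exists():
            raise FileNotFoundError(path)
        files = [path]

    frames: list[np.ndarray] = []
    depths: list[int] = []
    shapes: dict[tuple[int, int], list[str]] = {}
    for f in files:
        if f.lower().endswith((".tif", ".tiff")):
            data = tifffile.imread(f)
        else:
            data = iio.imread(f)
        pages = data if data.ndim == 3 and data.shape[-1] not in (3, 4) else [data]
        for page in pages:
            gray, depth = _to_gray_float(np.asarray(page), f)
            frames.append(gray)
            depths.append(depth)
            shapes.setdefault(gray.shape, []).append(f)
    if len(shapes) > 1:
        detail = "; ".join(f"{shp}: {fs[0]}" for shp, fs in shapes.items())
        raise ValueError(f"mixed frame shapes in stack ({detail})")
    if len(set(depths)) > 1:
        raise ValueError(f"mixed source bit depths in stack: {sorted(set(depths))}")
    return ImageStack(np.stack(frames), depths[0], frame_interval_s)


def write_stack(stack: ImageStack | np.ndarray, path: str | Path, bit_depth: int = 8) -> None:
    """Write frames as a multi-page TIFF at the requested bit depth."""
    frames = stack.frames if isinstance(stack, ImageStack) else np.asarray(stack, dtype=float)
    if bit_depth == 8:
        data = np.clip(np.round(frames * 255.0), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        data = np.clip(np.round(frames * 65535.0), 0, 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    tifffile.imwrite(str(path), data, photometric="minisblack")


def write_masks(masks: np.ndarray, out_dir: str | Path, prefix: str = "mask") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t, mask in enumerate(masks):
        iio.imwrite(out / f"{prefix}_{t:04d}.png", (np.asarray(mask, bool) * 255).astype(np.uint8))


def crop_stack(stack: ImageStack, box: tuple[int, int, int, int]) -> ImageStack:
    """Fixed-box crop (row0, col0, height, width) applied to every frame;
    single-cell fields are assumed prepared upstream with this utility."""
    r0, c0, hh, ww = box
    return ImageStack(stack.frames[:, r0 : r0 + hh, c0 : c0 + ww], stack.bit_depth_source, stack.frame_interval_s)
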