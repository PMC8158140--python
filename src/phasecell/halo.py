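"""Halo-artifact removal by tile-statistics K-means background correction.

Phase-contrast optics surround the dark cell body with a bright rim (the
halo) that confuses edge-based segmentation.  The frame is cut into small
tiles, each summarized by (mean, std) intensity statistics; K-means with
k = 2 separates homogeneous background tiles from tiles containing cell or
halo signal.  The mean intensity of the background tiles defines the
background image B(x, t); dividing the frame by B and clamping every ratio
>= 1 to exactly 1 flattens both the background and the bright halo while
cell pixels (darker than background) keep ratios < 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

__all__ = [
    "TileGrid",
    "TileClustering",
    "BackgroundField",
    "CorrectedImage",
    "tile_image",
    "cluster_tiles",
    "build_background",
    "divide_correct",
    "remove_halo",
]

_B_FLOOR = 1.0 / 255.0
_R_FLOOR = 1e-6


@dataclass
class TileGrid:
    """Raster-order tiling of one frame with per-tile statistics.

    ``features_raw`` holds (mean, std) per tile; ``features_z`` the same
    features z-scored across tiles (a zero-variance feature z-scores to 0).
    """

    tile_size: int
    frame_shape: tuple[int, int]
    boxes: list[tuple[int, int, int, int]]  # (row0, col0, height, width)
    features_raw: np.ndarray
    features_z: np.ndarray


@dataclass
class TileClustering:
    """Two-way K-means labelling of tiles; True marks background tiles."""

    is_background: np.ndarray
    centers: np.ndarray
    background_cluster_id: int


@dataclass
class BackgroundField:
    """Per-frame estimated background image B(x, t); strictly positive."""

    B: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.B <= 0):
            raise ValueError("background field must be strictly positive")


@dataclass
class CorrectedImage:
    """Ratio image I/B with values clamped into (0, 1]."""

    R: np.ndarray


def tile_image(frame: np.ndarray, tile_size: int = 16) -> TileGrid:
    """Cut a frame into raster-order tiles (edge tiles truncated) and compute
    z-scored (mean, std) features per tile."""
    frame = np.asarray(frame, dtype=float)
    if tile_size < 4:
        raise ValueError("tile_size must be >= 4")
    h, w = frame.shape
    if h < 2 * tile_size or w < 2 * tile_size:
        raise ValueError("frame must span at least 2 tiles in each dimension")
    boxes = []
    feats = []
    for r0 in range(0, h, tile_size):
        for c0 in range(0, w, tile_size):
            tile = frame[r0 : r0 + tile_size, c0 : c0 + tile_size]
            boxes.append((r0, c0, tile.shape[0], tile.shape[1]))
            feats.append((tile.mean(), tile.std()))
    raw = np.asarray(feats)
    std = raw.std(axis=0)
    z = np.zeros_like(raw)
    nonzero = std > 0
    z[:, nonzero] = (raw[:, nonzero] - raw.mean(axis=0)[nonzero]) / std[nonzero]
    return TileGrid(tile_size, (h, w), boxes, raw, z)


def cluster_tiles(grid: TileGrid, seed: int = 0) -> TileClustering:
    """Split tiles into background/foreground with k = 2 K-means.

    K-means (k-means++ init, 10 restarts) runs on the z-scored features; to
    make labels invariant to tile enumeration order the features are fitted
    in lexicographic order and tiles assigned to the nearest center.  The
    background cluster is the one with the lower mean raw std (background
    tiles are statistically homogeneous); ties go to the larger cluster,
    then to the cluster containing the tile of lowest raw std.
    """
    feats = grid.features_z
    if len(feats) < 4:
        raise ValueError("need at least 4 tiles for clustering")
    if np.allclose(feats, feats[0]):
        return TileClustering(
            np.ones(len(feats), dtype=bool), np.vstack([feats[0], feats[0]]), 0
        )
    order = np.lexsort((feats[:, 1], feats[:, 0]))
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    km.fit(feats[order])
    centers = km.cluster_centers_
    d = ((feats[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d.argmin(axis=1)
    if len(np.unique(labels)) < 2:
        return TileClustering(np.ones(len(feats), dtype=bool), centers, int(labels[0]))

    raw_std = grid.features_raw[:, 1]
    mean_std = [raw_std[labels == k].mean() for k in (0, 1)]
    if mean_std[0] != mean_std[1]:
        bg = int(np.argmin(mean_std))
    else:
        sizes = [(labels == k).sum() for k in (0, 1)]
        if sizes[0] != sizes[1]:
            bg = int(np.argmax(sizes))
        else:
            bg = int(labels[np.argmin(raw_std)])
    return TileClustering(labels == bg, centers, bg)


def build_background(
    frame: np.ndarray,
    clustering: TileClustering,
    grid: TileGrid,
    mode: str = "scalar",
) -> BackgroundField:
    """Estimate B(x, t) from background-labelled tiles.

    ``scalar`` (default): B is the constant mean intensity over all pixels of
    background tiles.  ``tilewise``: per-tile means with foreground tiles
    filled from the nearest background tile and Gaussian smoothing, for
    shaded fields.  B is floored at 1/255 so division is safe.
    """
    frame = np.asarray(frame, dtype=float)
    if not clustering.is_background.any():
        raise ValueError(
            "no background tiles found; try a different tile size"
        )
    if mode == "scalar":
        total, count = 0.0, 0
        for box, is_bg in zip(grid.boxes, clustering.is_background):
            if is_bg:
                r0, c0, th, tw = box
                total += frame[r0 : r0 + th, c0 : c0 + tw].sum()
                count += th * tw
        value = max(total / count, _B_FLOOR)
        return BackgroundField(np.full(frame.shape, value))
    if mode != "tilewise":
        raise ValueError("mode must be 'scalar' or 'tilewise'")

    n_rows = int(np.ceil(grid.frame_shape[0] / grid.tile_size))
    n_cols = int(np.ceil(grid.frame_shape[1] / grid.tile_size))
    means = grid.features_raw[:, 0].reshape(n_rows, n_cols)
    bg_mask = clustering.is_background.reshape(n_rows, n_cols)
    # fill foreground tiles from the nearest background tile
    _, (ir, ic) = ndimage.distance_transform_edt(~bg_mask, return_indices=True)
    filled = means[ir, ic]
    field = np.zeros(grid.frame_shape)
    for box, value in zip(grid.boxes, filled.ravel()):
        r0, c0, th, tw = box
        field[r0 : r0 + th, c0 : c0 + tw] = value
    field = ndimage.gaussian_filter(field, sigma=grid.tile_size / 2.0)
    return BackgroundField(np.maximum(field, _B_FLOOR))


def divide_correct(frame: np.ndarray, background: BackgroundField) -> CorrectedImage:
    """Ratio correction R = I/B with every value >= 1 (halo and background)
    set to exactly 1; cell pixels stay below 1; output clamped into (0, 1]."""
    R = np.asarray(frame, dtype=float) / background.B
    R = np.minimum(R, 1.0)
    return CorrectedImage(np.maximum(R, _R_FLOOR))


def remove_halo(
    frame: np.ndarray,
    tile_size: int = 16,
    seed: int = 0,
    mode: str = "scalar",
) -> tuple[CorrectedImage, BackgroundField, TileClustering]:
    """Full halo-elimination pass: tile -> cluster -> background -> divide."""
    grid = tile_image(frame, tile_size)
    clustering = cluster_tiles(grid, seed)
    background = build_background(frame, clustering, grid, mode)
    corrected = divide_correct(frame, background)
    return corrected, background, clustering
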