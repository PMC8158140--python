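"""Centroid trajectories and trajectory-comparison metrics.

The tracked point per frame is the mass center of the segmented cell: the
unweighted mean pixel coordinate of the filled mask (boundary plus
interior).  Two trajectories over the same frames are compared by the
per-time-step Euclidean distance, summarized as its mean, maximum and
sample variance (n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TrajectoryComparison",
    "centroid",
    "build_trajectory",
    "compare_trajectories",
]

DEFAULT_FRAME_INTERVAL_S = 120.0  # 2-minute capture interval


@dataclass
class Trajectory:
    """Time-ordered sub-pixel centroid positions of one cell."""

    frames: np.ndarray   # strictly increasing frame indices
    times_s: np.ndarray
    rows: np.ndarray
    cols: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.rows = np.asarray(self.rows, dtype=float)
        self.cols = np.asarray(self.cols, dtype=float)
        if not (len(self.frames) == len(self.times_s) == len(self.rows) == len(self.cols)):
            raise ValueError("trajectory columns must share one length")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def points(self) -> list[tuple[int, float, float, float]]:
        return list(zip(self.frames, self.times_s, self.rows, self.cols))

    def to_dataframe(self) -> pd.DataFrame:
        """CSV convention: x = column, y = row (image-viewer axes)."""
        return pd.DataFrame(
            {"frame": self.frames, "time_s": self.times_s, "x": self.cols, "y": self.rows}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["frame"].values, df["time_s"].values, df["y"].values, df["x"].values)


@dataclass
class TrajectoryComparison:
    """Per-step Euclidean differences and their Table-style summaries.

    ``variance`` is the sample variance (n-1 denominator) of the per-step
    pixel distances; its units are therefore pixels squared even though the
    distances themselves are pixels.
    """

    per_step_diff: np.ndarray
    average: float
    max_diff: float
    variance: float
    per_axis_diff: dict = field(default_factory=dict)


def centroid(mask: np.ndarray) -> tuple[float, float]:
    """Unweighted mean (row, col) of all mask pixels, at sub-pixel precision."""
    coords = np.argwhere(np.asarray(mask, dtype=bool))
    if len(coords) == 0:
        raise ValueError("cannot compute the centroid of an empty mask")
    r, c = coords.mean(axis=0)
    return float(r), float(c)


def build_trajectory(
    masks: np.ndarray | list[np.ndarray],
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> Trajectory:
    """Per-frame centroids with times ``frame_index * frame_interval_s``."""
    empty = [t for t, m in enumerate(masks) if not np.asarray(m, dtype=bool).any()]
    if empty:
        raise ValueError(f"empty masks at frames {empty}")
    points = np.array([centroid(m) for m in masks])
    n = len(points)
    frames = np.arange(n)
    return Trajectory(frames, frames * frame_interval_s, points[:, 0], points[:, 1])


def compare_trajectories(
    a: Trajectory, b: Trajectory, normalize_to_start: bool = False
) -> TrajectoryComparison:
    """Compare two trajectories over identical frames.

    Reports the per-frame Euclidean distance plus its mean, maximum and
    sample variance; per-axis signed differences are included for
    transparency.  With ``normalize_to_start`` both trajectories are first
    shifted to begin at the origin.
    """
    if len(a) != len(b) or np.any(a.frames != b.frames):
        raise ValueError("trajectories must cover identical frames")
    if len(a) < 2:
        raise ValueError("need at least 2 points to compare trajectories")
    ar, ac = a.rows.copy(), a.cols.copy()
    br, bc = b.rows.copy(), b.cols.copy()
    if normalize_to_start:
        ar -= ar[0]
        ac -= ac[0]
        br -= br[0]
        bc -= bc[0]
    dr = ar - br
    dc = ac - bc
    diffs = np.hypot(dr, dc)
    return TrajectoryComparison(
        per_step_diff=diffs,
        average=float(diffs.mean()),
        max_diff=float(diffs.max()),
        variance=float(diffs.var(ddof=1)),
        per_axis_diff={"row": dr, "col": dc},
    )
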