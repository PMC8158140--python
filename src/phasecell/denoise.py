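"""Mixed Poisson-Gaussian denoising: noise estimation, the generalized
Anscombe transform, and two-stage BM3D collaborative filtering.

The noise model is ``y = clean + n`` with ``Var(y | clean) = alpha * clean +
sigma**2``: a gain-scaled Poisson (shot-noise) component plus additive
Gaussian read noise.  ``estimate_noise`` fits (alpha, sigma) from homogeneous
image patches, ``anscombe_forward`` stabilizes the variance to ~1, and
``bm3d_denoise`` runs the classic two stages (hard-threshold collaborative
filtering producing a basic estimate, then Wiener filtering guided by it).

Every BM3D primitive (block distances, grouping, 3-D transforms, shrinkage,
weighted aggregation) is exposed as its own function so each step can be
checked against brute-force oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dct

__all__ = [
    "NoiseParams",
    "BM3DProfile",
    "BlockGroup",
    "estimate_noise",
    "estimate_noise_stack",
    "anscombe_forward",
    "anscombe_inverse",
    "block_distance",
    "noisy_distance_moments",
    "prefiltered_distance",
    "group_blocks",
    "ht_collaborative_filter",
    "ht_weight",
    "wiener_coefficients",
    "wiener_filter",
    "wiener_weight",
    "aggregate",
    "transform_3d",
    "inverse_transform_3d",
    "bm3d_denoise",
]

WEIGHT_CAP = 1e8  # cap on aggregation weights when sigma or ||W|| is zero


@dataclass(frozen=True)
class NoiseParams:
    """Parameters of the mixed noise model Var(y|x) = alpha*x + sigma**2.

    alpha is the Poisson gain and sigma the Gaussian standard deviation,
    both on the normalized [0, 1] intensity scale.
    """

    alpha: float
    sigma: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.sigma < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class BM3DProfile:
    """Tunable BM3D parameters (standard reference defaults).

    Thresholds ``tau_match_*`` are normalized squared-intensity distances on
    the [0, 1] scale; ``lambda_3d`` multiplies sigma to give the 3-D
    hard-threshold level.
    """

    block_size_ht: int = 8
    block_size_wien: int = 8
    block_step: int = 3
    search_window: int = 39
    max_group_size: int = 16
    tau_match_ht: float = 3000.0 / 255.0**2
    tau_match_wien: float = 400.0 / 255.0**2
    lambda_2d: float = 2.0
    lambda_3d: float = 2.7
    transform_2d: str = "dct"
    transform_1d: str = "haar"

    def __post_init__(self) -> None:
        if self.block_size_ht < 4 or self.block_size_wien < 4:
            raise ValueError("block sizes must be >= 4")
        if self.search_window <= max(self.block_size_ht, self.block_size_wien):
            raise ValueError("search_window must exceed the block size")
        if self.tau_match_ht <= 0 or self.tau_match_wien <= 0:
            raise ValueError("matching thresholds must be positive")
        m = self.max_group_size
        if m < 1 or (m & (m - 1)) != 0:
            raise ValueError("max_group_size must be a power of two")

    def block_size(self, stage: str) -> int:
        return self.block_size_ht if stage == "ht" else self.block_size_wien

    def tau_match(self, stage: str) -> float:
        return self.tau_match_ht if stage == "ht" else self.tau_match_wien


@dataclass
class BlockGroup:
    """A stack of mutually similar blocks anchored at a reference coordinate.

    ``member_coords`` is ordered (reference first, then increasing distance,
    raster order breaking ties) and indexes the leading axis of ``stack``,
    which has shape (n_members, n1, n1).
    """

    ref_coord: tuple[int, int]
    member_coords: list[tuple[int, int]]
    stack: np.ndarray

    def __post_init__(self) -> None:
        if tuple(self.ref_coord) not in {tuple(c) for c in self.member_coords}:
            raise ValueError("reference coordinate must be a group member")
        if self.stack.shape[0] != len(self.member_coords):
            raise ValueError("stack depth must equal the number of members")


# ---------------------------------------------------------------------------
# noise estimation
# ---------------------------------------------------------------------------


def _patch_stats(
    frame: np.ndarray, patch_size: int, keep_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """(mean, variance) of the homogeneous patches of one frame.

    Patches touching the intensity range limits are discarded (clipped
    pixels deflate the sample variance); of the rest, the ``keep_fraction``
    with the lowest gradient energy survive.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    nr, nc = frame.shape[0] // patch_size, frame.shape[1] // patch_size
    if nr * nc < 8:
        raise ValueError(
            "frame too small/heterogeneous: fewer than 8 usable patches"
        )
    patches = (
        frame[: nr * patch_size, : nc * patch_size]
        .reshape(nr, patch_size, nc, patch_size)
        .transpose(0, 2, 1, 3)
        .reshape(nr * nc, patch_size, patch_size)
    )
    saturated = np.any((patches <= 1e-3) | (patches >= 1.0 - 1e-3), axis=(1, 2))
    if (~saturated).sum() >= 8:
        patches = patches[~saturated]
    gy = np.diff(patches, axis=1)
    gx = np.diff(patches, axis=2)
    energy = (gy**2).mean(axis=(1, 2)) + (gx**2).mean(axis=(1, 2))
    means = patches.mean(axis=(1, 2))
    variances = patches.var(axis=(1, 2), ddof=1)
    n_keep = max(8, int(round(len(patches) * keep_fraction)))
    keep = np.argsort(energy, kind="stable")[:n_keep]
    return means, variances, energy, keep


def _wls_line(means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Precision-weighted fit of variance = alpha*mean + sigma2 with a
    relative-residual outlier trim (Var(s^2) ~ 2 v^2/(n-1) motivates 1/v^2
    weights)."""
    design = np.stack([means, np.ones_like(means)], axis=1)
    coef, *_ = np.linalg.lstsq(design, variances, rcond=None)
    for _ in range(2):
        pred = np.maximum(design @ coef, 1e-10)
        rel_resid = np.abs(variances - pred) / pred
        scale = np.median(rel_resid) + 1e-12
        ok = rel_resid <= 5.0 * scale
        if ok.sum() < 8:
            break
        w = 1.0 / np.maximum(pred[ok], 1e-10)
        coef, *_ = np.linalg.lstsq(
            design[ok] * w[:, None], variances[ok] * w, rcond=None
        )
    return coef


def _fit_noise_law(
    means: np.ndarray,
    variances: np.ndarray,
    energy: np.ndarray,
    keep: np.ndarray,
) -> NoiseParams:
    """Fit the noise law from patch statistics.

    The rank-based homogeneous subset bootstraps an initial line; patches
    are then re-admitted wherever their gradient energy is consistent with
    pure noise at their intensity (flat patches have E[energy] = 4 * var).
    The absolute test avoids the truncation bias a pure rank cut induces on
    the marginally-included patches, while still rejecting structure.
    """
    if means[keep].max() - means[keep].min() < 0.05:
        # one intensity level only: alpha is unidentifiable
        return NoiseParams(0.0, float(np.sqrt(max(variances[keep].mean(), 0.0))))
    coef = _wls_line(means[keep], variances[keep])
    pred = np.maximum(means * coef[0] + coef[1], 1e-10)
    flat = energy <= 5.0 * pred  # 25% head-room over the flat-patch mean
    if flat.sum() >= 8:
        coef = _wls_line(means[flat], variances[flat])
    alpha, sigma2 = coef
    if alpha < 0:
        alpha, sigma2 = 0.0, float(variances[keep].mean())
    if sigma2 < 0:
        sigma2 = 0.0
        m, v = means[keep], variances[keep]
        alpha = max(0.0, float((v * m).sum() / (m**2).sum()))
    return NoiseParams(float(alpha), float(np.sqrt(max(sigma2, 0.0))))


def estimate_noise(
    frame: np.ndarray,
    patch_size: int = 16,
    keep_fraction: float = 0.5,
) -> NoiseParams:
    """Estimate (alpha, sigma) from homogeneous patches of one frame.

    The frame is cut into non-overlapping ``patch_size`` squares; the half
    with the lowest gradient energy (most homogeneous) is kept, and
    ``variance = alpha * mean + sigma**2`` is fitted to their (mean, variance)
    pairs by precision-weighted least squares with outlier rejection and a
    non-negativity clamp.  When all kept patches share essentially one
    intensity level the linear fit is degenerate; the variance is then
    attributed entirely to the Gaussian term (alpha = 0).
    """
    return _fit_noise_law(*_patch_stats(frame, patch_size, keep_fraction))


def estimate_noise_stack(
    frames: np.ndarray, patch_size: int = 16, keep_fraction: float = 0.5
) -> NoiseParams:
    """Estimate over a whole stack by pooling every frame's homogeneous
    patches into a single fit - the multi-frame average of the per-frame
    procedure, with far better conditioning of the Gaussian floor."""
    stats = [_patch_stats(f, patch_size, keep_fraction) for f in frames]
    means = np.concatenate([s[0] for s in stats])
    variances = np.concatenate([s[1] for s in stats])
    energy = np.concatenate([s[2] for s in stats])
    offsets = np.cumsum([0] + [len(s[0]) for s in stats[:-1]])
    keep = np.concatenate([s[3] + off for s, off in zip(stats, offsets)])
    return _fit_noise_law(means, variances, energy, keep)


# ---------------------------------------------------------------------------
# Anscombe transform
# ---------------------------------------------------------------------------


def anscombe_forward(frame: np.ndarray, params: NoiseParams) -> np.ndarray:
    """Generalized Anscombe transform: f(x) = (2/a)*sqrt(a*x + 3/8*a^2 + s^2).

    For alpha = 0 the noise is already Gaussian and the frame is returned
    unchanged.  Negative square-root arguments are clamped to zero with a
    warning.
    """
    frame = np.asarray(frame, dtype=float)
    a, s = params.alpha, params.sigma
    if a == 0:
        return frame.copy()
    arg = a * frame + 0.375 * a**2 + s**2
    if np.any(arg < 0):
        warnings.warn("Anscombe argument < 0 at some pixels; clamped to 0")
        arg = np.maximum(arg, 0.0)
    return (2.0 / a) * np.sqrt(arg)


def anscombe_inverse(frame: np.ndarray, params: NoiseParams) -> np.ndarray:
    """Algebraic inverse of :func:`anscombe_forward` (identity for alpha=0)."""
    frame = np.asarray(frame, dtype=float)
    a, s = params.alpha, params.sigma
    if a == 0:
        return frame.copy()
    return (a / 4.0) * frame**2 - 0.375 * a - s**2 / a


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _transform_matrix(name: str, n: int) -> np.ndarray:
    """Orthonormal transform matrix applied as ``M @ x``."""
    if name == "dct":
        return dct(np.eye(n), axis=0, norm="ortho")
    if name == "haar":
        if n & (n - 1):
            raise ValueError("Haar transform requires a power-of-two length")
        h = np.array([[1.0]])
        while h.shape[0] < n:
            top = np.kron(h, [1.0, 1.0])
            bot = np.kron(np.eye(h.shape[0]), [1.0, -1.0])
            h = np.vstack([top, bot]) / np.sqrt(2.0)
        return h
    raise ValueError(f"unknown transform {name!r}")


def _forward_2d(blocks: np.ndarray, profile: BM3DProfile, stage: str) -> np.ndarray:
    """2-D transform of a (..., n1, n1) block array."""
    t = _transform_matrix(profile.transform_2d, profile.block_size(stage))
    return np.einsum("ij,...jk,lk->...il", t, blocks, t)


def _inverse_2d(coefs: np.ndarray, profile: BM3DProfile, stage: str) -> np.ndarray:
    t = _transform_matrix(profile.transform_2d, profile.block_size(stage))
    return np.einsum("ji,...jk,kl->...il", t, coefs, t)


def transform_3d(stack: np.ndarray, profile: BM3DProfile, stage: str = "ht") -> np.ndarray:
    """Separable 3-D transform of a (K, n1, n1) stack: 2-D per block, then a
    1-D transform across the stack axis (K must be a power of two for Haar)."""
    c2 = _forward_2d(stack, profile, stage)
    h = _transform_matrix(profile.transform_1d, stack.shape[0])
    return np.tensordot(h, c2, axes=(1, 0))


def inverse_transform_3d(coefs: np.ndarray, profile: BM3DProfile, stage: str = "ht") -> np.ndarray:
    h = _transform_matrix(profile.transform_1d, coefs.shape[0])
    c2 = np.tensordot(h.T, coefs, axes=(1, 0))
    return _inverse_2d(c2, profile, stage)


# ---------------------------------------------------------------------------
# block distances and grouping
# ---------------------------------------------------------------------------


def block_distance(ref: np.ndarray, other: np.ndarray, n1: int | None = None) -> float:
    """Squared l2 distance between two n1 x n1 blocks, normalized by n1**2."""
    ref = np.asarray(ref, dtype=float)
    other = np.asarray(other, dtype=float)
    if ref.shape != other.shape:
        raise ValueError("blocks must have identical shapes")
    if n1 is None:
        n1 = ref.shape[0]
    return float(np.sum((ref - other) ** 2) / n1**2)


def noisy_distance_moments(
    true_distance: float, sigma: float, n1: int
) -> tuple[float, float]:
    """Expected value and variance of the noisy block distance.

    For non-overlapping blocks whose pixels carry independent N(0, sigma^2)
    noise, the normalized squared distance has mean ``d + 2*sigma^2`` and
    variance ``8*sigma^4/n1^2 + 8*sigma^2*d/n1^2`` (d = true distance).
    Diagnostic only; used to sanity-check matching thresholds.
    """
    expected = true_distance + 2.0 * sigma**2
    variance = 8.0 * sigma**4 / n1**2 + 8.0 * sigma**2 * true_distance / n1**2
    return expected, variance


def _hard_threshold(coefs: np.ndarray, threshold: float) -> np.ndarray:
    return np.where(np.abs(coefs) > threshold, coefs, 0.0)


def prefiltered_distance(
    ref: np.ndarray,
    other: np.ndarray,
    profile: BM3DProfile,
    sigma: float,
) -> float:
    """Block distance computed on hard-thresholded 2-D transform coefficients.

    Coarse prefiltering suppresses the noise floor of the distance: each
    block is transformed, coefficients below ``lambda_2d * sigma`` are
    zeroed, and the normalized squared distance of the thresholded
    coefficient arrays is returned.  With sigma = 0 this equals
    :func:`block_distance` (Parseval, orthonormal transform).
    """
    n1 = profile.block_size_ht
    if ref.shape != (n1, n1) or other.shape != (n1, n1):
        raise ValueError("blocks must match profile.block_size_ht")
    thr = profile.lambda_2d * sigma
    cr = _hard_threshold(_forward_2d(np.asarray(ref, float), profile, "ht"), thr)
    co = _hard_threshold(_forward_2d(np.asarray(other, float), profile, "ht"), thr)
    return float(np.sum((cr - co) ** 2) / n1**2)


class _FrameCache:
    """Per-frame precomputation shared by all reference blocks of a stage.

    Holds the sliding-window view of the frame and, for the hard-threshold
    stage, the thresholded 2-D transform coefficients used by the
    prefiltered matching distance.
    """

    def __init__(self, frame: np.ndarray, profile: BM3DProfile, sigma: float, stage: str):
        n1 = profile.block_size(stage)
        self.n1 = n1
        self.stage = stage
        self.shape = frame.shape
        self.windows = sliding_window_view(np.ascontiguousarray(frame, dtype=float), (n1, n1))
        if stage == "ht":
            coefs = _forward_2d(self.windows, profile, "ht")
            self.dist_basis = _hard_threshold(coefs, profile.lambda_2d * sigma)
        else:
            # Wiener-stage matching uses plain pixel distances on the guide
            self.dist_basis = self.windows

    def distances(self, ref: tuple[int, int], coords: np.ndarray) -> np.ndarray:
        base = self.dist_basis[ref[0], ref[1]]
        cand = self.dist_basis[coords[:, 0], coords[:, 1]]
        return np.sum((cand - base) ** 2, axis=(1, 2)) / self.n1**2


def _candidate_coords(
    ref: tuple[int, int], shape: tuple[int, int], profile: BM3DProfile, n1: int
) -> np.ndarray:
    """Search-window candidate top-left coordinates at block_step granularity,
    anchored on the reference and clipped to fully-inside positions."""
    half = (profile.search_window - n1) // 2
    step = profile.block_step
    out = []
    for axis, size in enumerate(shape):
        lo, hi = 0, size - n1
        ks = np.arange(-(half // step), half // step + 1)
        vals = ref[axis] + ks * step
        out.append(vals[(vals >= lo) & (vals <= hi)])
    rr, cc = np.meshgrid(out[0], out[1], indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)


def _largest_pow2(n: int) -> int:
    return 1 << (n.bit_length() - 1)


def _select_members(
    cache: _FrameCache,
    ref_coord: tuple[int, int],
    profile: BM3DProfile,
    tau: float,
) -> list[tuple[int, int]]:
    coords = _candidate_coords(ref_coord, cache.shape, profile, cache.n1)
    d = cache.distances(ref_coord, coords)
    keep = d <= tau
    coords, d = coords[keep], d[keep]
    raster = coords[:, 0] * cache.shape[1] + coords[:, 1]
    order = np.lexsort((raster, d))
    coords = coords[order]
    k = min(len(coords), profile.max_group_size)
    k = _largest_pow2(max(k, 1))
    members = [tuple(int(v) for v in c) for c in coords[:k]]
    if tuple(ref_coord) not in members:
        members = [tuple(ref_coord)] + members[: k - 1] if k > 1 else [tuple(ref_coord)]
    return members


def group_blocks(
    frame: np.ndarray,
    ref_coord: tuple[int, int],
    profile: BM3DProfile,
    sigma: float,
    stage: str = "ht",
    guide: np.ndarray | None = None,
) -> BlockGroup:
    """Match blocks similar to the reference within the search window.

    Candidates are scanned at ``block_step`` granularity; those whose
    distance is at or below the stage's tau_match are kept (smallest
    distances first when more than ``max_group_size`` match, raster order
    breaking ties, the group truncated to a power-of-two size for the 1-D
    transform).  In the Wiener stage distances are measured on ``guide``
    (the basic estimate) while ``stack`` is cut from ``frame``.
    """
    frame = np.asarray(frame, dtype=float)
    if stage not in ("ht", "wien"):
        raise ValueError("stage must be 'ht' or 'wien'")
    if stage == "wien":
        if guide is None:
            raise ValueError("Wiener-stage grouping requires a guide image")
        cache = _FrameCache(np.asarray(guide, float), profile, sigma, "wien")
    else:
        cache = _FrameCache(frame, profile, sigma, "ht")
    members = _select_members(cache, ref_coord, profile, profile.tau_match(stage))
    n1 = profile.block_size(stage)
    windows = sliding_window_view(frame, (n1, n1))
    stack = np.stack([windows[r, c] for r, c in members])
    return BlockGroup(tuple(ref_coord), members, stack)


# ---------------------------------------------------------------------------
# collaborative filtering
# ---------------------------------------------------------------------------


def ht_collaborative_filter(
    group: BlockGroup, profile: BM3DProfile, sigma: float
) -> tuple[np.ndarray, int]:
    """Hard-threshold collaborative filtering of a block group.

    The group is taken to the separable 3-D transform domain, coefficients
    with magnitude at or below ``lambda_3d * sigma`` are zeroed (the DC
    coefficient is exempt so the group mean survives), and the stack is
    transformed back.  Returns the filtered stack and the number of retained
    non-zero coefficients.
    """
    coefs = transform_3d(group.stack, profile, "ht")
    thr = profile.lambda_3d * sigma
    filtered = _hard_threshold(coefs, thr)
    filtered[0, 0, 0] = coefs[0, 0, 0]  # DC exempt
    n_retained = int(np.count_nonzero(filtered))
    return inverse_transform_3d(filtered, profile, "ht"), n_retained


def ht_weight(n_retained: int, sigma: float) -> float:
    """Aggregation weight 1/(sigma^2 * N) for N >= 1 retained coefficients,
    1 otherwise; capped when sigma = 0."""
    if n_retained < 0:
        raise ValueError("n_retained must be non-negative")
    if n_retained == 0:
        return 1.0
    if sigma == 0:
        return WEIGHT_CAP
    return min(1.0 / (sigma**2 * n_retained), WEIGHT_CAP)


def wiener_coefficients(basic_coefs: np.ndarray, sigma: float) -> np.ndarray:
    """Wiener shrinkage W = T^2 / (T^2 + sigma^2) from basic-estimate
    3-D coefficients; W in [0, 1), -> 1 as sigma -> 0 for non-zero T."""
    t2 = np.asarray(basic_coefs, dtype=float) ** 2
    if sigma == 0:
        return (t2 > 0).astype(float)
    return t2 / (t2 + sigma**2)


def wiener_filter(
    noisy_group: BlockGroup, shrinkage: np.ndarray, profile: BM3DProfile
) -> np.ndarray:
    """Element-wise Wiener shrinkage of the noisy group in the 3-D transform
    domain, followed by the inverse transform."""
    coefs = transform_3d(noisy_group.stack, profile, "wien")
    if shrinkage.shape != coefs.shape:
        raise ValueError("shrinkage stack shape must match the group")
    return inverse_transform_3d(shrinkage * coefs, profile, "wien")


def wiener_weight(shrinkage: np.ndarray, sigma: float) -> float:
    """Aggregation weight (sigma^2 * ||W||_2^2)^-1, capped when degenerate."""
    norm2 = float(np.sum(np.asarray(shrinkage, dtype=float) ** 2))
    if sigma == 0 or norm2 == 0:
        return WEIGHT_CAP
    return min(1.0 / (sigma**2 * norm2), WEIGHT_CAP)


def aggregate(
    groups: list[tuple[BlockGroup, float]], frame_shape: tuple[int, int]
) -> np.ndarray:
    """Weighted aggregation of overlapping filtered block estimates.

    Each group's stack values are accumulated at the members' supports with
    the group weight; the estimate is numerator/denominator.  A pixel not
    covered by any block violates the scan contract and raises.
    """
    num = np.zeros(frame_shape, dtype=float)
    den = np.zeros(frame_shape, dtype=float)
    for group, weight in groups:
        n1 = group.stack.shape[1]
        for idx, (r, c) in enumerate(group.member_coords):
            num[r : r + n1, c : c + n1] += weight * group.stack[idx]
            den[r : r + n1, c : c + n1] += weight
    if np.any(den == 0):
        raise ValueError("aggregation left uncovered pixels")
    return num / den


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _ref_grid(size: int, n1: int, step: int) -> np.ndarray:
    pos = list(range(0, size - n1 + 1, step))
    if pos[-1] != size - n1:
        pos.append(size - n1)  # force edge coverage
    return np.asarray(pos)


def _bm3d_stage(
    noisy: np.ndarray,
    sigma: float,
    profile: BM3DProfile,
    stage: str,
    guide: np.ndarray | None = None,
) -> np.ndarray:
    n1 = profile.block_size(stage)
    match_frame = guide if stage == "wien" else noisy
    cache = _FrameCache(match_frame, profile, sigma, stage)
    noisy_windows = sliding_window_view(np.ascontiguousarray(noisy, dtype=float), (n1, n1))
    if stage == "wien":
        guide_windows = sliding_window_view(np.ascontiguousarray(guide, dtype=float), (n1, n1))
    tau = profile.tau_match(stage)
    num = np.zeros(noisy.shape, dtype=float)
    den = np.zeros(noisy.shape, dtype=float)
    rows = _ref_grid(noisy.shape[0], n1, profile.block_step)
    cols = _ref_grid(noisy.shape[1], n1, profile.block_step)
    for r in rows:
        for c in cols:
            members = _select_members(cache, (int(r), int(c)), profile, tau)
            idx = np.array(members)
            stack = noisy_windows[idx[:, 0], idx[:, 1]]
            if stage == "ht":
                group = BlockGroup((int(r), int(c)), members, stack)
                filtered, n_ret = ht_collaborative_filter(group, profile, sigma)
                w = ht_weight(n_ret, sigma)
            else:
                basic_stack = guide_windows[idx[:, 0], idx[:, 1]]
                shrink = wiener_coefficients(
                    transform_3d(basic_stack, profile, "wien"), sigma
                )
                group = BlockGroup((int(r), int(c)), members, stack)
                filtered = wiener_filter(group, shrink, profile)
                w = wiener_weight(shrink, sigma)
            for k, (mr, mc) in enumerate(members):
                num[mr : mr + n1, mc : mc + n1] += w * filtered[k]
                den[mr : mr + n1, mc : mc + n1] += w
    if np.any(den == 0):
        raise ValueError("aggregation left uncovered pixels")
    return num / den


def bm3d_denoise(
    frame: np.ndarray,
    params: NoiseParams,
    profile: BM3DProfile | None = None,
    return_basic: bool = False,
):
    """Two-stage BM3D with Anscombe stabilization for mixed noise.

    For alpha > 0 the frame is taken through the generalized Anscombe
    transform (unit noise variance), affinely rescaled to [0, 1] (sigma
    rescaled to 1/(max-min)) so the matching thresholds keep their [0, 1]
    meaning, filtered, rescaled back and inverse-transformed.  Pure-Gaussian
    frames (alpha = 0) are filtered directly.  Output clipped to [0, 1].
    """
    if profile is None:
        profile = BM3DProfile()
    frame = np.asarray(frame, dtype=float)
    if params.alpha > 0:
        transformed = anscombe_forward(frame, params)
        lo, hi = float(transformed.min()), float(transformed.max())
        if hi - lo < 1e-12:
            out = frame.copy()
            return (out, out.copy()) if return_basic else out
        work = (transformed - lo) / (hi - lo)
        sigma = 1.0 / (hi - lo)  # unit post-Anscombe noise, rescaled
    else:
        work = frame
        sigma = params.sigma

    basic = _bm3d_stage(work, sigma, profile, "ht")
    final = _bm3d_stage(work, sigma, profile, "wien", guide=basic)

    def _restore(img: np.ndarray) -> np.ndarray:
        if params.alpha > 0:
            img = img * (hi - lo) + lo
            img = anscombe_inverse(img, params)
        return np.clip(img, 0.0, 1.0)

    out = _restore(final)
    if return_basic:
        return out, _restore(basic)
    return out
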