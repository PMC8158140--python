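"""Noise estimation, Anscombe transform, and the BM3D building blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasecell.denoise import (
    BM3DProfile,
    BlockGroup,
    NoiseParams,
    aggregate,
    anscombe_forward,
    anscombe_inverse,
    block_distance,
    bm3d_denoise,
    estimate_noise,
    estimate_noise_stack,
    group_blocks,
    ht_collaborative_filter,
    ht_weight,
    inverse_transform_3d,
    noisy_distance_moments,
    prefiltered_distance,
    transform_3d,
    wiener_coefficients,
    wiener_filter,
    wiener_weight,
)
from phasecell.phantom import PhantomSpec, flat_calibration_stack, generate_phantom


# ---------------------------------------------------------------------------
# noise estimation
# ---------------------------------------------------------------------------


def test_estimate_noise_zero_on_noise_free_constant_image():
    params = estimate_noise(np.full((128, 128), 0.5))
    assert params.alpha == 0.0
    assert params.sigma == pytest.approx(0.0, abs=1e-12)


def test_estimate_noise_pure_gaussian_phantom():
    out = generate_phantom(PhantomSpec(noise_alpha=0.0, noise_sigma=0.02, seed=1))
    params = estimate_noise(out.stack[0])
    assert params.alpha <= 0.002
    assert 0.016 <= params.sigma <= 0.024


def test_estimate_noise_rejects_tiny_frames():
    with pytest.raises(ValueError, match="patches"):
        estimate_noise(np.zeros((20, 20)))


def test_estimate_noise_stack_recovers_mixed_parameters():
    noisy, _ = flat_calibration_stack(alpha=0.01, sigma=0.01, seed=5)
    params = estimate_noise_stack(noisy)
    assert params.alpha == pytest.approx(0.01, rel=0.20)
    assert params.sigma == pytest.approx(0.01, rel=0.20)


# ---------------------------------------------------------------------------
# Anscombe transform
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x,expected",
    [(0.0, 2.0 * np.sqrt(3.0 / 8.0)), (10.0, 2.0 * np.sqrt(10.375))],
)
def test_anscombe_closed_form_pure_poisson(x, expected):
    out = anscombe_forward(np.array([[x]]), NoiseParams(1.0, 0.0))
    assert out[0, 0] == pytest.approx(expected, abs=1e-9)


def test_anscombe_alpha_zero_is_identity():
    frame = np.linspace(0, 1, 16).reshape(4, 4)
    params = NoiseParams(0.0, 0.05)
    assert np.array_equal(anscombe_forward(frame, params), frame)
    assert np.array_equal(anscombe_inverse(frame, params), frame)


@given(
    alpha=st.floats(1e-3, 2.0),
    sigma=st.floats(0.0, 0.5),
    x=st.floats(0.0, 10.0),
)
@settings(max_examples=50, derandomize=True, deadline=None)
def test_anscombe_round_trip_property(alpha, sigma, x):
    params = NoiseParams(alpha, sigma)
    arr = np.array([[x]])
    assert anscombe_inverse(anscombe_forward(arr, params), params)[0, 0] == pytest.approx(
        x, abs=1e-9
    )


def test_anscombe_round_trip_on_phantom_frame():
    out = generate_phantom(PhantomSpec(noise_alpha=0.01, noise_sigma=0.02, seed=3, n_frames=1))
    params = NoiseParams(0.01, 0.02)
    rt = anscombe_inverse(anscombe_forward(out.stack[0], params), params)
    assert np.abs(rt - out.stack[0]).max() < 1e-9


def test_anscombe_stabilizes_poisson_variance(rng):
    for lam in (10.0, 20.0):
        samples = rng.poisson(lam, size=100_000).astype(float)
        transformed = anscombe_forward(samples[None, :], NoiseParams(1.0, 0.0))
        assert 0.9 <= transformed.var() <= 1.1


# ---------------------------------------------------------------------------
# block distances
# ---------------------------------------------------------------------------


def test_block_distance_worked_example():
    b1 = np.array([[1.0, 2.0], [3.0, 4.0]])
    b2 = np.array([[1.0, 2.0], [3.0, 5.0]])
    assert block_distance(b1, b2, n1=2) == pytest.approx(0.25)
    assert block_distance(b1, b1) == 0.0


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=20, derandomize=True, deadline=None)
def test_block_distance_symmetric(seed):
    r = np.random.default_rng(seed)
    a, b = r.random((4, 4)), r.random((4, 4))
    assert block_distance(a, b) == pytest.approx(block_distance(b, a))


def test_block_distance_shape_mismatch():
    with pytest.raises(ValueError):
        block_distance(np.zeros((4, 4)), np.zeros((8, 8)))


def test_noisy_distance_moments_worked_examples():
    assert noisy_distance_moments(0.3, 0.0, 8) == (0.3, 0.0)
    expected, variance = noisy_distance_moments(0.0, 0.1, 8)
    assert expected == pytest.approx(0.02)
    assert variance == pytest.approx(1.25e-5)


def test_noisy_distance_moments_match_simulation(rng):
    """The chi-square moments must match distances between independently
    noised copies of one block."""
    n1, sigma = 8, 0.1
    base = rng.random((n1, n1))
    other = base + 0.05
    true_d = block_distance(base, other)
    dists = []
    for _ in range(4000):
        za = base + rng.normal(0, sigma, (n1, n1))
        zb = other + rng.normal(0, sigma, (n1, n1))
        dists.append(block_distance(za, zb))
    dists = np.asarray(dists)
    expected, variance = noisy_distance_moments(true_d, sigma, n1)
    assert dists.mean() == pytest.approx(expected, rel=0.05)
    assert dists.var(ddof=1) == pytest.approx(variance, rel=0.15)


def test_prefiltered_distance_identical_blocks_and_parseval(rng):
    profile = BM3DProfile()
    a = rng.random((8, 8))
    b = rng.random((8, 8))
    assert prefiltered_distance(a, a, profile, 0.1) == 0.0
    # sigma = 0: no thresholding, orthonormal transform => Parseval
    assert prefiltered_distance(a, b, profile, 0.0) == pytest.approx(
        block_distance(a, b), abs=1e-12
    )


def test_prefiltered_distance_suppresses_noise(rng):
    """On a smooth (transform-sparse) block the hard-thresholded distance
    discards the noise floor that inflates the plain distance."""
    profile = BM3DProfile()
    base = 0.25 + 0.5 * np.add.outer(np.linspace(0, 1, 8), np.linspace(0, 1, 8)) / 2
    sigma = 0.1
    wins = 0
    for _ in range(100):
        za = base + rng.normal(0, sigma, (8, 8))
        zb = base + rng.normal(0, sigma, (8, 8))
        if prefiltered_distance(za, zb, profile, sigma) < block_distance(za, zb):
            wins += 1
    assert wins >= 90


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


def _brute_force_group(frame, ref, profile, sigma, stage="ht", guide=None):
    """Independent matcher: enumerate candidates, distances, selection."""
    n1 = profile.block_size(stage)
    match = frame if stage == "ht" else guide
    half = (profile.search_window - n1) // 2
    step = profile.block_step
    cands = []
    for axis in (0, 1):
        lo, hi = 0, frame.shape[axis] - n1
        vals = [
            ref[axis] + k * step
            for k in range(-(half // step), half // step + 1)
            if lo <= ref[axis] + k * step <= hi
        ]
        cands.append(vals)
    ref_block = match[ref[0] : ref[0] + n1, ref[1] : ref[1] + n1]
    scored = []
    for r in cands[0]:
        for c in cands[1]:
            blk = match[r : r + n1, c : c + n1]
            if stage == "ht":
                d = prefiltered_distance(ref_block, blk, profile, sigma)
            else:
                d = block_distance(ref_block, blk)
            if d <= profile.tau_match(stage):
                scored.append((d, r * frame.shape[1] + c, (r, c)))
    scored.sort()
    k = min(len(scored), profile.max_group_size)
    k = 1 << (max(k, 1).bit_length() - 1)
    return [s[2] for s in scored[:k]]


def test_group_blocks_matches_brute_force_on_two_texture_image(rng):
    profile = BM3DProfile(search_window=17, block_step=2, block_size_ht=4, block_size_wien=4)
    frame = np.where(np.add.outer(np.arange(24), np.arange(24)) % 2 == 0, 0.3, 0.7)
    frame = frame + rng.normal(0, 0.02, frame.shape)
    for ref in [(0, 0), (5, 7), (12, 3), (20, 20)]:
        for stage in ("ht", "wien"):
            guide = frame if stage == "wien" else None
            group = group_blocks(frame, ref, profile, 0.02, stage, guide)
            expected = _brute_force_group(frame, ref, profile, 0.02, stage, guide)
            assert group.member_coords == expected, (ref, stage)


def test_group_on_constant_image_fills_to_max_size():
    profile = BM3DProfile()
    group = group_blocks(np.full((64, 64), 0.5), (20, 20), profile, 0.05)
    assert len(group.member_coords) == profile.max_group_size


def test_group_unique_block_with_zero_threshold():
    profile = BM3DProfile(tau_match_ht=1e-12)
    frame = np.zeros((48, 48))
    frame[20:28, 20:28] = np.arange(64).reshape(8, 8) / 64.0
    group = group_blocks(frame, (20, 20), profile, 0.0)
    assert group.member_coords == [(20, 20)]


# ---------------------------------------------------------------------------
# collaborative filtering and aggregation
# ---------------------------------------------------------------------------


def _make_group(stack, ref=(0, 0)):
    coords = [(ref[0], ref[1] + i) for i in range(stack.shape[0])]
    return BlockGroup(coords[0], coords, stack)


def test_transform_3d_round_trip(rng):
    profile = BM3DProfile()
    stack = rng.random((8, 8, 8))
    rt = inverse_transform_3d(transform_3d(stack, profile), profile)
    assert np.abs(rt - stack).max() < 1e-10


def test_ht_filter_zero_sigma_is_identity(rng):
    profile = BM3DProfile()
    stack = rng.random((4, 8, 8))
    group = _make_group(stack)
    filtered, n_ret = ht_collaborative_filter(group, profile, 0.0)
    assert np.abs(filtered - stack).max() < 1e-10
    coefs = transform_3d(stack, profile)
    assert n_ret == np.count_nonzero(coefs)


def test_ht_filter_preserves_constant_group():
    profile = BM3DProfile()
    stack = np.full((4, 8, 8), 0.6)
    filtered, _ = ht_collaborative_filter(_make_group(stack), profile, 0.1)
    assert np.abs(filtered - 0.6).max() < 1e-10  # all energy in exempt DC


def test_ht_filter_denoises_constant_blocks(rng):
    profile = BM3DProfile()
    clean = np.full((16, 8, 8), 0.5)
    noisy = clean + rng.normal(0, 0.1, clean.shape)
    filtered, _ = ht_collaborative_filter(_make_group(noisy), profile, 0.1)
    mse_in = np.mean((noisy - clean) ** 2)
    mse_out = np.mean((filtered - clean) ** 2)
    assert mse_out * 5 <= mse_in


def test_ht_weight_values():
    assert ht_weight(4, 0.1) == pytest.approx(25.0)
    assert ht_weight(0, 0.1) == 1.0
    assert ht_weight(3, 0.0) == 1e8
    weights = [ht_weight(n, 0.2) for n in range(1, 30)]
    assert all(a >= b for a, b in zip(weights, weights[1:]))


def test_wiener_coefficients_values():
    assert wiener_coefficients(np.array(0.0), 0.1) == 0.0
    assert wiener_coefficients(np.array(0.3), 0.1) == pytest.approx(0.9)
    assert wiener_coefficients(np.array(0.3), 0.0) == 1.0  # sigma -> 0 limit


def test_wiener_filter_identity_and_zero(rng):
    profile = BM3DProfile()
    stack = rng.random((4, 8, 8))
    group = _make_group(stack)
    ones = np.ones((4, 8, 8))
    assert np.abs(wiener_filter(group, ones, profile) - stack).max() < 1e-10
    assert np.abs(wiener_filter(group, np.zeros_like(ones), profile)).max() < 1e-12


def test_wiener_oracle_shrinkage_beats_hard_threshold(rng):
    profile = BM3DProfile()
    clean = np.full((8, 8, 8), 0.5)
    noisy = clean + rng.normal(0, 0.1, clean.shape)
    shrink = wiener_coefficients(transform_3d(clean, profile, "wien"), 0.1)
    wien = wiener_filter(_make_group(noisy), shrink, profile)
    ht, _ = ht_collaborative_filter(_make_group(noisy), profile, 0.1)
    assert np.mean((wien - clean) ** 2) < np.mean((ht - clean) ** 2)


def test_wiener_weight_values():
    w = np.zeros((2, 1, 1))
    w[0, 0, 0], w[1, 0, 0] = 1.0, 1.0
    assert wiener_weight(w, 0.1) == pytest.approx(50.0)
    ones = np.ones((4, 2, 2))  # K = 16 elements
    assert wiener_weight(ones, 0.1) == pytest.approx(1.0 / (0.01 * 16))
    assert wiener_weight(np.zeros((2, 2, 2)), 0.1) == 1e8


def test_aggregate_matches_brute_force_oracle(rng):
    """12x12 frame: aggregation equals a per-pixel weighted-mean loop."""
    n1 = 4
    frame_shape = (12, 12)
    groups = []
    coords_all = [(r, c) for r in (0, 3, 6, 8) for c in (0, 4, 8)]
    for i, ref in enumerate(coords_all):
        members = [ref]
        if ref[0] + 1 <= frame_shape[0] - n1:
            members.append((ref[0] + 1, ref[1]))
        stack = rng.random((len(members), n1, n1))
        groups.append((BlockGroup(ref, members, stack), 0.5 + i * 0.25))
    result = aggregate(groups, frame_shape)

    num = np.zeros(frame_shape)
    den = np.zeros(frame_shape)
    for group, w in groups:
        for k, (r, c) in enumerate(group.member_coords):
            for dr in range(n1):
                for dc in range(n1):
                    num[r + dr, c + dc] += w * group.stack[k, dr, dc]
                    den[r + dr, c + dc] += w
    assert np.allclose(result, num / den, atol=1e-12)


def test_aggregate_single_group_and_equal_weight_overlap():
    stack = np.full((1, 4, 4), 0.3)
    single = aggregate([(BlockGroup((0, 0), [(0, 0)], stack), 2.0)], (4, 4))
    assert np.allclose(single, 0.3)

    a = BlockGroup((0, 0), [(0, 0)], np.full((1, 4, 4), 0.2))
    b = BlockGroup((0, 2), [(0, 2)], np.full((1, 4, 4), 0.6))
    out = aggregate([(a, 1.0), (b, 1.0)], (4, 6))
    assert np.allclose(out[:, 2:4], 0.4)  # equal-weight mean on the overlap


def test_aggregate_uncovered_pixel_raises():
    stack = np.zeros((1, 4, 4))
    with pytest.raises(ValueError, match="uncovered"):
        aggregate([(BlockGroup((0, 0), [(0, 0)], stack), 1.0)], (8, 8))


# ---------------------------------------------------------------------------
# end-to-end BM3D
# ---------------------------------------------------------------------------


def test_bm3d_sigma_zero_is_identity(small_phantom):
    frame = small_phantom.clean_stack[0]
    out = bm3d_denoise(frame, NoiseParams(0.0, 0.0))
    assert np.abs(out - frame).max() < 1e-8


def test_bm3d_output_within_input_range(small_phantom, rng):
    frame = np.clip(small_phantom.clean_stack[0] + rng.normal(0, 0.05, (96, 96)), 0, 1)
    out = bm3d_denoise(frame, NoiseParams(0.0, 0.05))
    assert out.min() >= 0.0 and out.max() <= 1.0
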