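"""Sharpening, iterative thresholding, and binarization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apicalnet.preprocessing import (
    HighPassSpec,
    apply_highpass,
    binarize,
    iterative_threshold,
    preprocess,
    sharpen_difference,
    highpass_transfer,
)
from apicalnet.synthetic import generate_phantom, random_phantom_spec


# ---------------------------------------------------------------------------
# transfer function

@pytest.mark.parametrize("shape", [(4, 4), (7, 5), (16, 16), (1, 9)])
@pytest.mark.parametrize("d0", [4.0, 8.0, 240.0])
@pytest.mark.parametrize("convention", ["paper_literal", "standard_gaussian"])
def test_transfer_gain_zero_at_center_and_bounded(shape, d0, convention):
    h = highpass_transfer(*shape, HighPassSpec(d0, convention))
    assert h.shape == shape
    assert h[shape[0] // 2, shape[1] // 2] == 0.0
    assert np.all(h >= 0.0) and np.all(h < 1.0)


def test_transfer_gain_saturates_without_exceeding_one():
    # at tiny cutoffs the exp underflows and the gain rounds to exactly 1
    h = highpass_transfer(64, 64, HighPassSpec(d0=0.5))
    assert h.max() == 1.0 and np.all(h <= 1.0)


def test_transfer_literal_value():
    # gain = 1 - exp(-D^2 / (2 d0)); with d0 = 8 and D^2 = 16 this is 1 - 1/e
    h = highpass_transfer(17, 17, HighPassSpec(d0=8.0, exponent_convention="paper_literal"))
    assert h[8 + 4, 8] == pytest.approx(1.0 - np.exp(-1.0), abs=1e-12)
    # standard convention divides by 2 d0^2 instead
    hs = highpass_transfer(17, 17, HighPassSpec(d0=8.0, exponent_convention="standard_gaussian"))
    assert hs[8 + 4, 8] == pytest.approx(1.0 - np.exp(-16.0 / 128.0), abs=1e-12)


def test_transfer_radial_symmetry_and_monotonicity():
    h = highpass_transfer(33, 33, HighPassSpec(d0=10.0))
    c = 16
    for d in range(1, 16):
        assert h[c + d, c] == pytest.approx(h[c - d, c], abs=1e-14)
        assert h[c, c + d] == pytest.approx(h[c, c - d], abs=1e-14)
        assert h[c, c + d] > h[c, c + d - 1]


def test_transfer_rejects_bad_d0():
    with pytest.raises(ValueError):
        HighPassSpec(d0=0.0)
    with pytest.raises(ValueError):
        HighPassSpec(d0=-3.0)


# ---------------------------------------------------------------------------
# frequency-domain filtering vs a brute-force DFT oracle

def _brute_force_highpass(image, spec):
    """Per-frequency double loop: centered DFT x gain, inverse by loops."""
    img = np.asarray(image, dtype=float)
    m, n = img.shape
    gain = np.empty((m, n))
    for u in range(m):
        for v in range(n):
            d2 = (u - m // 2) ** 2 + (v - n // 2) ** 2
            denom = 2 * spec.d0 if spec.exponent_convention == "paper_literal" \
                else 2 * spec.d0**2
            gain[u, v] = 1.0 - np.exp(-d2 / denom)
    fx = np.zeros((m, n), dtype=complex)
    for u in range(m):
        for v in range(n):
            s = 0.0j
            for x in range(m):
                for y in range(n):
                    s += img[x, y] * np.exp(-2j * np.pi * (u * x / m + v * y / n))
            fx[(u + m // 2) % m, (v + n // 2) % n] = s  # centered spectrum
    fx *= gain
    out = np.zeros((m, n))
    for x in range(m):
        for y in range(n):
            s = 0.0j
            for u in range(m):
                for v in range(n):
                    fu, fv = (u + m // 2) % m, (v + n // 2) % n
                    s += fx[fu, fv] * np.exp(2j * np.pi * (u * x / m + v * y / n))
            out[x, y] = s.real / (m * n)
    return out


@pytest.mark.parametrize("shape", [(4, 4), (5, 3), (8, 8)])
def test_highpass_matches_brute_force_oracle(rng, shape):
    img = rng.integers(0, 256, shape).astype(np.uint8)
    spec = HighPassSpec(d0=6.0)
    got = apply_highpass(img, spec)
    want = _brute_force_highpass(img, spec)
    assert np.allclose(got, want, atol=1e-8)


def test_highpass_blocks_constant_image():
    out = apply_highpass(np.full((12, 9), 128, dtype=np.uint8), HighPassSpec())
    assert np.max(np.abs(out)) < 1e-6


def test_highpass_keeps_checkerboard_energy():
    img = np.indices((8, 8)).sum(axis=0) % 2 * 255
    out = apply_highpass(img, HighPassSpec(d0=6.0))
    assert np.abs(out).max() > 50.0


# ---------------------------------------------------------------------------
# difference image

def test_sharpen_identity_when_filtered_zero(rng):
    img = rng.integers(0, 256, (6, 6)).astype(np.uint8)
    assert np.array_equal(sharpen_difference(img, np.zeros((6, 6))), img)


def test_sharpen_clips_at_zero():
    img = np.full((3, 3), 100, dtype=np.uint8)
    out = sharpen_difference(img, np.full((3, 3), 150.0))
    assert np.all(out == 0)


def test_sharpen_hand_grid():
    img = np.array([[10, 200, 30], [0, 255, 130], [90, 60, 5]], dtype=np.uint8)
    filt = np.array([[-20.0, 100.0, 300.0], [5.5, -1.2, 30.0], [90.0, -60.0, 5.0]])
    want = np.array([[30, 100, 0], [0, 255, 100], [0, 120, 0]])
    assert np.array_equal(sharpen_difference(img, filt), want)
    want_rev = np.array([[0, 0, 255], [6, 0, 0], [0, 0, 0]])
    assert np.array_equal(
        sharpen_difference(img, filt, "filtered_minus_original"), want_rev
    )


def test_sharpen_shape_mismatch():
    with pytest.raises(ValueError):
        sharpen_difference(np.zeros((2, 2)), np.zeros((3, 2)))


# ---------------------------------------------------------------------------
# iterative threshold

def test_threshold_symmetric_two_level_image():
    img = np.array([0, 255] * 8, dtype=np.uint8).reshape(4, 4)
    trace = iterative_threshold(img)
    assert trace.t0 == 127.5
    assert trace.final_t == 127.5
    assert trace.converged


def test_threshold_hand_iteration():
    # pixels [10, 10, 50, 90, 90]: T0 = 50, then
    # low mean = (10+10+50)/3 = 23.333, high mean = 90 -> T1 = 56.667 = T2
    img = np.array([[10, 10, 50, 90, 90]], dtype=np.uint8)
    trace = iterative_threshold(img, epsilon=0.5)
    assert trace.t0 == 50.0
    assert trace.iterates[0] == pytest.approx(56.6667, abs=1e-3)
    assert trace.final_t == pytest.approx(56.6667, abs=1e-3)
    assert trace.converged
    assert trace.z_max0 == 90 and trace.z_min0 == 10


def test_threshold_constant_image():
    trace = iterative_threshold(np.full((5, 5), 77, dtype=np.uint8))
    assert trace.final_t == 77.0
    assert trace.converged
    assert trace.iterates == ()


def test_threshold_rejects_empty_and_bad_epsilon():
    with pytest.raises(ValueError):
        iterative_threshold(np.empty((0, 3)))
    with pytest.raises(ValueError):
        iterative_threshold(np.ones((2, 2)), epsilon=0.0)


def _two_group_update(pixels, t):
    """Independent tally of (mean_low + mean_high)/2 with low = (<= t)."""
    low = [p for p in pixels if p <= t]
    high = [p for p in pixels if p > t]
    if not low or not high:
        return t
    return (sum(low) / len(low) + sum(high) / len(high)) / 2.0


@pytest.mark.parametrize("seed", range(10))
def test_threshold_fixed_point_on_random_images(seed):
    img = np.random.default_rng(seed).integers(0, 256, (16, 16)).astype(np.uint8)
    eps = 0.5
    trace = iterative_threshold(img, epsilon=eps)
    pixels = [int(p) for p in img.ravel()]
    assert abs(_two_group_update(pixels, trace.final_t) - trace.final_t) < eps
    assert min(pixels) <= trace.final_t <= max(pixels)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 255), min_size=2, max_size=64), st.integers(0, 10**6))
def test_threshold_final_within_range_property(pixels, _salt):
    img = np.array(pixels, dtype=np.uint8).reshape(1, -1)
    trace = iterative_threshold(img, epsilon=0.5)
    assert min(pixels) <= trace.final_t <= max(pixels)
    assert abs(_two_group_update(pixels, trace.final_t) - trace.final_t) < 0.5


# ---------------------------------------------------------------------------
# binarization

def test_binarize_examples():
    assert np.array_equal(
        binarize(np.array([[10, 200]]), 56.67), np.array([[0, 255]])
    )
    # pixels equal to the threshold fall in the dark group
    assert np.all(binarize(np.full((3, 3), 100), 100.0) == 0)


def test_binarize_idempotent_and_two_valued(rng):
    img = rng.integers(0, 256, (9, 9)).astype(np.uint8)
    b = binarize(img, 127.0)
    assert set(np.unique(b)) <= {0, 255}
    assert np.array_equal(binarize(b, 127.0), b)


def test_binarize_rejects_nonfinite_threshold():
    with pytest.raises(ValueError):
        binarize(np.zeros((2, 2)), np.nan)


# ---------------------------------------------------------------------------
# whole-chain property on phantoms

@pytest.mark.parametrize("seed", range(20))
def test_preprocess_separates_teeth_from_gaps(seed):
    """Sharpen -> threshold -> binarize leaves every truth gap column dark."""
    from apicalnet.synthetic import generate_phantom

    spec = random_phantom_spec(seed)
    image, truth = generate_phantom(spec)
    result = preprocess(image)
    sums = result.binary.sum(axis=0)
    assert all(sums[g] == 0 for g in truth.gap_columns)
    # teeth survive: the center of each truth region stays bright
    assert all(sums[(a + b) // 2] > 0 for a, b in truth.tooth_regions)
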