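"""Preprocessing pipeline: Prewitt, bisigmoid, resize, normalize, mask."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dropclass import (
    PreprocessConfig,
    SyntheticSceneConfig,
    apply_circular_mask,
    bisigmoid,
    bisigmoid_range,
    normalize,
    preprocess_batch,
    preprocess_droplet,
    prewitt_horizontal,
    render_droplet,
    resize_image,
)
from dropclass.preprocess import _sigmoid_pair, minimal_config

CFG = PreprocessConfig()

small_images = arrays(
    np.float64,
    (12, 12),
    elements=st.floats(min_value=-1e5, max_value=1e5, allow_nan=False),
)


# ---------------------------------------------------------------- prewitt


def test_prewitt_constant_image_is_zero_where_neighborhood_constant():
    """The derivative of a constant vanishes; with zero-padded borders this
    holds everywhere the 3x3 neighborhood lies inside the image."""
    resp = prewitt_horizontal(np.full((9, 9), 123.0))
    np.testing.assert_array_equal(resp[1:-1, :], 0)


def test_prewitt_column_constant_stripe_is_zero_in_interior():
    """An ideal beadline stripe is constant along each column; the interior
    response of the horizontal-edge kernel is identically zero."""
    img = np.full((5, 5), 100.0)
    img[:, 2] = 40.0  # vertical stripe
    resp = prewitt_horizontal(img)
    np.testing.assert_array_equal(resp[1:-1, :], 0)


def test_prewitt_horizontal_step_response_is_3h_with_sign_asymmetry():
    """Hand evaluation: out(i,j) = sum over 3 columns of (row below - row
    above); an interior step of height h gives magnitude 3h on the rows
    adjacent to the step, with opposite signs for rising vs falling steps."""
    h = 50.0
    up = np.zeros((5, 5))
    up[2:, :] = h  # step upward going down the rows
    resp_up = prewitt_horizontal(up)
    assert resp_up[1, 2] == 3 * h
    assert resp_up[2, 2] == 3 * h
    assert resp_up[3, 2] == 0
    down = up[::-1, :]
    resp_down = prewitt_horizontal(down)
    assert resp_down[2, 2] == -3 * h  # the white/black edge asymmetry
    with pytest.raises(ValueError):
        prewitt_horizontal(np.zeros((2, 5)))


# --------------------------------------------------------------- bisigmoid


def test_bisigmoid_zero_arguments_give_half_scale():
    assert _sigmoid_pair(0.0, 0.0, CFG) == pytest.approx(12000.0)


def test_bisigmoid_range_is_open_interval_of_width_2x_scale():
    lo, hi = bisigmoid_range(CFG)
    assert (lo, hi) == (-12000.0, 36000.0)
    assert (hi - lo) / 2 == CFG.sigmoid_scale


@settings(deadline=None, max_examples=50, derandomize=True)
@given(small_images)
def test_bisigmoid_output_bounded_and_no_overflow(img):
    lo, hi = bisigmoid_range(CFG)
    with np.errstate(over="raise"):
        out = bisigmoid(img, CFG)
    assert np.all(out > lo - 1e-9) and np.all(out < hi + 1e-9)


def test_bisigmoid_constant_image_fallback_is_zero():
    np.testing.assert_array_equal(bisigmoid(np.full((7, 7), 5.0), CFG), 0)


def test_bisigmoid_exponent_cap_respected():
    img = np.zeros((5, 5))
    img[0, 0] = 1e9  # would give alpha ~ 1.7e6 without the cap
    with np.errstate(over="raise"):
        out = bisigmoid(img, CFG)
    assert np.all(np.isfinite(out))


# ------------------------------------------------------------------ resize


def test_resize_is_near_identity_at_native_size(rng):
    img = rng.uniform(0, 65535, (55, 55))
    np.testing.assert_allclose(resize_image(img, 55), img, atol=1e-6)


def test_resize_constant_preserved_and_shape():
    out = resize_image(np.full((110, 110), 777.0), 55)
    assert out.shape == (55, 55)
    np.testing.assert_allclose(out, 777.0)


# --------------------------------------------------------------- normalize


def test_normalize_maps_extremes_exactly(rng):
    img = rng.uniform(100, 60000, (20, 20))
    out = normalize(img)
    assert out[np.unravel_index(img.argmax(), img.shape)] == 65535.0
    assert out[np.unravel_index(img.argmin(), img.shape)] == 0.0


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    small_images,
    st.floats(min_value=0.01, max_value=100.0),
    st.floats(min_value=-1e4, max_value=1e4),
)
def test_normalize_affine_invariance(img, a, b):
    if img.max() == img.min():
        return
    np.testing.assert_allclose(normalize(a * img + b), normalize(img), atol=1.0)


def test_normalize_idempotent(rng):
    img = rng.uniform(0, 1000, (15, 15))
    once = normalize(img)
    np.testing.assert_allclose(normalize(once), once, atol=1.0)


def test_normalize_constant_image_warns_and_zeros(caplog):
    with caplog.at_level("WARNING"):
        out = normalize(np.full((5, 5), 9.0))
    np.testing.assert_array_equal(out, 0)
    assert any("constant" in r.message for r in caplog.records)


# -------------------------------------------------------------------- mask


def test_mask_zeroes_corners_keeps_center():
    img = np.full((55, 55), 3.0)
    out = apply_circular_mask(img, 5)
    assert out[0, 0] == out[0, -1] == out[-1, 0] == out[-1, -1] == 0
    assert out[27, 27] == 3.0


def test_mask_survivor_count_matches_lattice_oracle():
    side, reduction = 55, 5
    out = apply_circular_mask(np.ones((side, side)), reduction)
    # independent brute-force lattice enumeration
    c = (side - 1) / 2
    r2 = (side / 2 - reduction) ** 2
    expected = sum(
        1 for y in range(side) for x in range(side) if (y - c) ** 2 + (x - c) ** 2 < r2
    )
    assert int(out.sum()) == expected


def test_mask_rejects_excessive_reduction():
    with pytest.raises(ValueError):
        apply_circular_mask(np.ones((10, 10)), 5)


# ---------------------------------------------------------------- pipeline


@pytest.mark.parametrize("mode", ["full", "minimal"])
def test_pipeline_shape_range_and_masked_annulus(mode):
    drop = render_droplet(SyntheticSceneConfig(n_cells=2, seed=6))
    cfg = replace(CFG, mode=mode)
    out = preprocess_droplet(drop.image, cfg)
    assert out.shape == (55, 55)
    assert out.min() >= 0 and out.max() <= 65535
    if mode == "full":
        c = 27.0
        yy, xx = np.ogrid[:55, :55]
        outside = (yy - c) ** 2 + (xx - c) ** 2 >= (55 / 2 - 5) ** 2
        np.testing.assert_array_equal(out[outside], 0)


def test_batch_stacking_shape():
    drops = [
        render_droplet(SyntheticSceneConfig(n_cells=i % 3, seed=i)).image for i in range(4)
    ]
    assert preprocess_batch(drops, CFG).shape == (4, 55, 55)


def test_full_pipeline_suppresses_ideal_beadline():
    """Droplets differing only by a column-constant beadline preprocess to
    nearly identical images (difference only via per-image statistics)."""
    for n_cells, seed in [(0, 11), (1, 12), (3, 13)]:
        base = SyntheticSceneConfig(
            n_cells=n_cells, noise_sd=0.0, beadline_irregularity=0.0, seed=seed
        )
        with_line = preprocess_droplet(render_droplet(replace(base, beadline=True)).image, CFG)
        without = preprocess_droplet(render_droplet(replace(base, beadline=False)).image, CFG)
        mad = np.abs(with_line - without).mean()
        assert mad < 0.01 * CFG.norm_max


def test_pipeline_is_deterministic():
    drop = render_droplet(SyntheticSceneConfig(n_cells=1, seed=3))
    a = preprocess_droplet(drop.image, CFG)
    b = preprocess_droplet(drop.image, CFG)
    np.testing.assert_array_equal(a, b)


def test_minimal_config_flips_mode_only():
    mc = minimal_config(CFG)
    assert mc.mode == "minimal"
    assert mc.sigmoid_scale == CFG.sigmoid_scale
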