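"""Morphology post-processing against a definitional sliding-window oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import ndimage

from jcwmh.maskops import (
    MorphologyConfig,
    binarize,
    closing,
    dilate,
    erode,
    opening,
    postprocess_tissue,
    postprocess_ventricles,
    postprocess_wmh,
)
from jcwmh.rasters import BinaryMask, ProbabilityMap, VolumeGeometry

from conftest import GEOM09, mask

# -- independent oracle: shift-and-combine over element offsets -------------


def naive_dilate(pixels: np.ndarray, size: int) -> np.ndarray:
    """y[i,j] = OR of x over the size x size window (zero padding)."""
    r = size // 2
    h, w = pixels.shape
    out = np.zeros_like(pixels)
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            src = pixels[
                max(0, -di) : h - max(0, di), max(0, -dj) : w - max(0, dj)
            ]
            out[max(0, di) : h - max(0, -di), max(0, dj) : w - max(0, -dj)] |= src
    return out


def naive_erode_direct(pixels: np.ndarray, size: int) -> np.ndarray:
    """y[i,j] = AND of x over the window; out-of-image counts as False."""
    r = size // 2
    h, w = pixels.shape
    out = np.ones_like(pixels)
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            shifted = np.zeros_like(pixels)
            src = pixels[
                max(0, -di) : h - max(0, di), max(0, -dj) : w - max(0, dj)
            ]
            shifted[max(0, di) : h - max(0, -di), max(0, dj) : w - max(0, -dj)] = src
            out &= shifted
    return out


@pytest.mark.parametrize("size", [3, 5, 9])
def test_morphology_matches_sliding_window_oracle(size):
    """Dilation/erosion/opening/closing equal the naive oracle bit-exactly."""
    rng = np.random.default_rng(777)
    for density in (0.05, 0.3, 0.7):
        for _ in range(17):
            px = rng.random((64, 64)) < density
            m = mask(px)
            assert np.array_equal(dilate(m, size).pixels, naive_dilate(px, size))
            expected_erode = naive_erode_direct(px, size)
            assert np.array_equal(erode(m, size).pixels, expected_erode)
            assert np.array_equal(
                opening(m, size).pixels,
                naive_dilate(naive_erode_direct(px, size), size),
            )
            assert np.array_equal(
                closing(m, size).pixels,
                naive_erode_direct(naive_dilate(px, size), size),
            )


def test_binarize_threshold_is_inclusive():
    geom = GEOM09
    pm = ProbabilityMap(np.full((4, 4), 0.5), geom)
    assert binarize(pm, 0.5).pixels.all()
    two_level = ProbabilityMap(
        np.where(np.eye(4, dtype=bool), 0.8, 0.2), geom
    )
    out = binarize(two_level, 0.6)
    assert np.array_equal(out.pixels, np.eye(4, dtype=bool))
    assert binarize(pm, 0.0).pixels.all()


def test_wmh_dilation_of_point_is_the_element(geom):
    px = np.zeros((11, 11), bool)
    px[5, 5] = True
    out = postprocess_wmh(mask(px), MorphologyConfig())
    expected = np.zeros((11, 11), bool)
    expected[3:8, 3:8] = True
    assert np.array_equal(out.pixels, expected)


def test_dilation_extensivity_and_empty_propagation(rng):
    cfg = MorphologyConfig()
    for _ in range(10):
        px = rng.random((48, 48)) < 0.1
        m = mask(px)
        assert np.all(px <= postprocess_wmh(m, cfg).pixels)
    empty = mask(np.zeros((32, 32), bool))
    assert postprocess_wmh(empty, cfg).count() == 0
    assert postprocess_ventricles(empty, cfg).count() == 0


def test_morphology_monotonicity(rng):
    """A subset-of B implies op(A) subset-of op(B) for every op."""
    cfg = MorphologyConfig()
    for _ in range(10):
        b = rng.random((48, 48)) < 0.4
        a = b & (rng.random((48, 48)) < 0.5)
        for op in (
            lambda m: dilate(m, 5),
            lambda m: erode(m, 3),
            lambda m: opening(m, 3),
            lambda m: closing(m, 3),
            lambda m: postprocess_wmh(m, cfg),
        ):
            assert np.all(op(mask(a)).pixels <= op(mask(b)).pixels)


def test_tissue_postprocess_examples(geom):
    cfg = MorphologyConfig()
    # isolated pixel removed by the size-3 opening
    lone = np.zeros((16, 16))
    lone[8, 8] = 1.0
    assert postprocess_tissue(ProbabilityMap(lone, geom), 0.5, cfg).count() == 0
    # large solid square is invariant
    solid = np.zeros((30, 30))
    solid[5:25, 5:25] = 1.0
    out = postprocess_tissue(ProbabilityMap(solid, geom), 0.5, cfg)
    assert np.array_equal(out.pixels, solid > 0)
    # one-pixel interior hole is filled by the closing
    holed = solid.copy()
    holed[15, 15] = 0.0
    out = postprocess_tissue(ProbabilityMap(holed, geom), 0.5, cfg)
    assert np.array_equal(out.pixels, solid > 0)


def test_ventricle_expansion_exceeds_10mm_by_distance_transform(geom):
    """Default closing+dilation pushes every original boundary point >10 mm
    into the interior of the new mask at 0.9 mm spacing."""
    px = np.zeros((96, 96), bool)
    yy, xx = np.ogrid[:96, :96]
    px[(yy - 48) ** 2 + (xx - 48) ** 2 <= 10**2] = True
    out = postprocess_ventricles(mask(px), MorphologyConfig())
    assert np.all(px <= out.pixels)
    # distance from each original boundary pixel to the new exterior
    dist_to_outside = ndimage.distance_transform_edt(
        out.pixels, sampling=(0.9, 0.9)
    )
    boundary = px & ~ndimage.binary_erosion(px)
    assert dist_to_outside[boundary].min() > 10.0


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    px=arrays(bool, (24, 24), elements=st.booleans()),
    size=st.sampled_from([3, 5]),
)
def test_morphology_oracle_property(px, size):
    """Hypothesis-driven oracle agreement plus duality dilate(~x) = ~erode(x)
    complement relationship under zero padding."""
    m = mask(px)
    assert np.array_equal(dilate(m, size).pixels, naive_dilate(px, size))
    assert np.array_equal(erode(m, size).pixels, naive_erode_direct(px, size))
    # extensivity / anti-extensivity
    assert np.all(px <= dilate(m, size).pixels)
    assert np.all(erode(m, size).pixels <= px)


def test_config_validation():
    with pytest.raises(ValueError):
        MorphologyConfig(gm_threshold=0.9, wm_threshold=0.1)
    with pytest.raises(ValueError):
        MorphologyConfig(wmh_dilate_size=4)
    with pytest.raises(ValueError):
        MorphologyConfig(vent_dilate_iters=0)
    cfg = MorphologyConfig()
    assert cfg.vent_expansion_mm(0.9) > 10.0
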