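"""Pixel classification and the seven per-drawing metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from emodraw.color_features import (
    BlankCanvasError,
    classify_image,
    classify_pixel,
    color_fill,
    color_percentages,
    count_colors,
    drawn_mask,
    extract_features,
    image_coverage,
    prominent_color,
    saturation_brightness,
)
from emodraw.image_io import RasterImage, hsv_to_rgb_opencv
from emodraw.palette import EXPRESSIVE_COLORS, UNCLASSIFIED, ColorPalette


def brute_force_classify(hsv, palette):
    """Independent oracle: first containing range in evaluation order."""
    for r in palette.ranges:
        if r.contains(tuple(hsv)):
            return r.name
    return UNCLASSIFIED


@pytest.mark.parametrize(
    "hsv, expected",
    [
        ((0, 255, 255), "red"),
        ((120, 255, 255), "blue"),
        ((150, 255, 255), "red"),       # upper red interval
        ((0, 0, 0), "black"),
        ((0, 0, 255), "white"),
        ((0, 0, 128), "gray"),
        ((90, 35, 150), "unclassified"),  # S between gray max and blue min
        ((23, 200, 60), "black"),         # dark yellow: black precedence
    ],
)
def test_classify_pixel_examples(hsv, expected, palette):
    assert classify_pixel(hsv, palette) == expected


def test_classify_matches_brute_force_oracle(palette):
    rng = np.random.default_rng(3)
    hs = rng.integers(0, 181, 10_000)
    sv = rng.integers(0, 256, (10_000, 2))
    triples = np.column_stack([hs, sv])
    codes = classify_image(triples.reshape(-1, 1, 3), palette).ravel()
    names = palette.color_names
    for t, code in zip(triples[:500], codes[:500]):
        got = names[code] if code >= 0 else UNCLASSIFIED
        assert got == brute_force_classify(t, palette)
    # full agreement checked vectorised: every triple's code matches the
    # first containing range
    lo, hi = palette.bound_arrays()
    inside = np.all(
        (triples[:, None, :] >= lo[None]) & (triples[:, None, :] <= hi[None]), axis=2
    )
    first = np.where(inside.any(1), inside.argmax(1), -1)
    expected = np.array(
        [names.index(palette.ranges[f].name) if f >= 0 else -1 for f in first]
    )
    assert np.array_equal(codes, expected)


def test_out_of_scale_component_rejected(palette):
    with pytest.raises(ValueError):
        classify_pixel((181, 0, 0), palette)
    with pytest.raises(ValueError):
        classify_pixel((0, 256, 0), palette)


def _hsv_img(rows):
    return np.array(rows, dtype=np.int64)


def test_drawn_mask_cases(palette):
    all_white = np.full((10, 10, 3), (0, 0, 255), dtype=np.int64)
    assert not drawn_mask(all_white, palette).any()
    one_black = all_white.copy()
    one_black[3, 4] = (0, 0, 0)
    assert drawn_mask(one_black, palette).sum() == 1
    near_white = all_white.copy()
    near_white[0, 0] = (0, 20, 240)   # S=20<=30, V=240>=230: still canvas
    assert not drawn_mask(near_white, palette)[0, 0]


def _image_30red_20blue_50white():
    hsv = np.full((10, 10, 3), (0, 0, 255), dtype=np.int64)
    flat = hsv.reshape(-1, 3)
    flat[:30] = (0, 255, 255)
    flat[30:50] = (120, 255, 255)
    return hsv


def test_color_percentages_mixed_image(palette):
    pct = color_percentages(_image_30red_20blue_50white(), palette)
    assert pct["red"] == 60.0
    assert pct["blue"] == 40.0
    assert all(pct[c] == 0.0 for c in EXPRESSIVE_COLORS if c not in ("red", "blue"))


def test_color_percentages_single_pixel_and_blank(palette):
    hsv = np.full((5, 5, 3), (0, 0, 255), dtype=np.int64)
    hsv[0, 0] = (0, 255, 255)
    assert color_percentages(hsv, palette)["red"] == 100.0
    with pytest.raises(BlankCanvasError):
        color_percentages(np.full((5, 5, 3), (0, 0, 255), dtype=np.int64), palette)


def test_color_percentages_equal_quarters(palette):
    hsv = np.zeros((10, 10, 3), dtype=np.int64)
    flat = hsv.reshape(-1, 3)
    flat[:25] = (0, 255, 255)
    flat[25:50] = (23, 255, 255)
    flat[50:75] = (60, 255, 255)
    flat[75:] = (120, 255, 255)
    pct = color_percentages(hsv, palette)
    for c in ("red", "yellow", "green", "blue"):
        assert pct[c] == 25.0


def test_prominent_color_and_tie_break():
    assert prominent_color({"red": 60.0, "blue": 40.0}) == "red"
    assert prominent_color({"red": 100.0}) == "red"
    # exact tie: fixed palette order puts red first
    assert prominent_color({"red": 50.0, "blue": 50.0}) == "red"
    assert prominent_color({"gray": 50.0, "black": 50.0}) == "gray"


def test_count_colors_threshold():
    assert count_colors({"red": 60.0, "blue": 40.0}) == 2
    assert count_colors({"red": 100.0}) == 1
    assert count_colors({"red": 99.5, "yellow": 0.5}) == 1
    assert count_colors({"red": 99.5, "yellow": 0.5}, min_share=0.4) == 2


def test_saturation_brightness_means(palette):
    hsv = np.zeros((10, 10, 3), dtype=np.int64)
    flat = hsv.reshape(-1, 3)
    flat[:50] = (0, 255, 255)
    flat[50:] = (0, 0, 255)
    mask = np.ones((10, 10), dtype=bool)
    s, v = saturation_brightness(hsv, mask)
    assert s == pytest.approx(50.0)
    assert v == pytest.approx(100.0)
    full = np.full((4, 4, 3), (0, 255, 255), dtype=np.int64)
    assert saturation_brightness(full, np.ones((4, 4), bool)) == (100.0, 100.0)
    dark = np.zeros((4, 4, 3), dtype=np.int64)
    assert saturation_brightness(dark, np.ones((4, 4), bool)) == (0.0, 0.0)
    with pytest.raises(BlankCanvasError):
        saturation_brightness(hsv, np.zeros((10, 10), bool))


def _ring_mask():
    """Closed 6x6 outline on a 10x10 canvas: 20 drawn px enclosing 16."""
    m = np.zeros((10, 10), dtype=bool)
    m[2:8, 2:8] = True
    m[3:7, 3:7] = False
    assert m.sum() == 20
    return m


def test_fill_and_coverage_ring_case():
    m = _ring_mask()
    assert color_fill(m) == 20.0
    assert image_coverage(m) == 36.0


def test_fill_and_coverage_solid_blob_and_empty():
    m = np.zeros((10, 10), dtype=bool)
    m[0:5, 0:5] = True
    assert color_fill(m) == image_coverage(m) == 25.0
    empty = np.zeros((10, 10), dtype=bool)
    assert color_fill(empty) == 0.0
    assert image_coverage(empty) == 0.0
    assert image_coverage(np.ones((10, 10), bool)) == 100.0


@given(
    arrays(bool, (12, 12), elements=st.booleans()),
    st.sampled_from([1, 2]),
)
@settings(max_examples=150, derandomize=True)
def test_fill_never_exceeds_coverage(mask, connectivity):
    assert color_fill(mask) <= image_coverage(mask, connectivity=connectivity) + 1e-12


def test_metrics_invariant_under_rotation_and_transposition(palette):
    rng = np.random.default_rng(4)
    rgb = rng.integers(0, 256, size=(20, 30, 3)).astype(np.uint8)
    base = extract_features(RasterImage(rgb, "base"), palette)
    for variant in (np.rot90(rgb).copy(), rgb.transpose(1, 0, 2).copy()):
        other = extract_features(RasterImage(variant, "var"), palette)
        assert other.color_pct == base.color_pct
        assert other.color_fill_pct == base.color_fill_pct
        assert other.image_coverage_pct == base.image_coverage_pct
        assert other.saturation_pct == pytest.approx(base.saturation_pct)
        assert other.brightness_pct == pytest.approx(base.brightness_pct)


def test_color_percentages_sum_to_100_exactly(palette):
    rng = np.random.default_rng(5)
    for _ in range(25):
        rgb = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
        img = RasterImage(rgb)
        try:
            fv = extract_features(img, palette)
        except BlankCanvasError:
            continue
        assert abs(sum(fv.color_pct.values()) - 100.0) < 1e-9


def test_extract_features_composed_example(palette):
    hsv = _image_30red_20blue_50white()
    rgb = hsv_to_rgb_opencv(hsv.astype(float))
    fv = extract_features(RasterImage(rgb, "mix"), palette)
    assert fv.prominent_color == "red"
    assert fv.color_pct["red"] == 60.0
    assert fv.color_pct["blue"] == 40.0
    assert fv.color_fill_pct == 50.0
    assert fv.image_coverage_pct == 50.0
    assert fv.saturation_pct == 100.0
    assert fv.brightness_pct == 100.0
    assert fv.n_colors == 2
    assert fv.unclassified_pct == 0.0


def test_blank_canvas_raises(palette):
    white = np.full((8, 8, 3), 255, dtype=np.uint8)
    with pytest.raises(BlankCanvasError):
        extract_features(RasterImage(white, "blank"), palette)
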