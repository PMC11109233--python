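"""Per-drawing color-composition features.

A drawing is summarised by seven metrics:

* prominent color — the expressive color holding the largest share of
  classified drawn pixels (ties broken by fixed palette order);
* color percentages — each expressive color's share of the classified
  drawn pixels, summing to exactly 100;
* number of colors used — expressive colors above a small share
  threshold (default 1% of drawn pixels, to discard JPEG edge debris);
* saturation and brightness percentages — mean S and V over drawn
  pixels, rescaled to 0-100;
* color fill percentage — drawn pixels over canvas pixels;
* image coverage percentage — drawn pixels plus enclosed blank holes
  over canvas pixels (holes found by flood-filling the background from
  the canvas border).

"Drawn" means outside the white range, the blank canvas. Pixels that are
drawn but fall in no color range (saturation/value gaps between the
achromatic and chromatic boxes, typically JPEG compression noise) count
toward fill, coverage and the saturation/brightness means, but are
excluded from both numerator and denominator of the color percentages —
which is what makes the seven shares sum to exactly 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np
from scipy import ndimage

from .image_io import RasterImage, rgb_to_hsv_opencv
from .palette import EXPRESSIVE_COLORS, UNCLASSIFIED, WHITE, ColorPalette

__all__ = [
    "FeatureVector",
    "BlankCanvasError",
    "classify_pixel",
    "classify_image",
    "drawn_mask",
    "color_percentages",
    "prominent_color",
    "count_colors",
    "saturation_brightness",
    "color_fill",
    "image_coverage",
    "extract_features",
]


class BlankCanvasError(ValueError):
    """Raised when a drawing contains no usable drawn pixels."""


@dataclass
class FeatureVector:
    """The per-drawing metrics, all percentages on a 0-100 scale."""

    source_id: str
    prominent_color: str
    color_pct: dict[str, float]
    n_colors: int
    saturation_pct: float
    brightness_pct: float
    color_fill_pct: float
    image_coverage_pct: float
    unclassified_pct: float

    def as_row(self) -> dict[str, float | str | int]:
        row: dict[str, float | str | int] = {
            "source_id": self.source_id,
            "prominent_color": self.prominent_color,
        }
        for c in EXPRESSIVE_COLORS:
            row[f"pct_{c}"] = self.color_pct[c]
        row.update(
            n_colors=self.n_colors,
            saturation_pct=self.saturation_pct,
            brightness_pct=self.brightness_pct,
            color_fill_pct=self.color_fill_pct,
            image_coverage_pct=self.image_coverage_pct,
            unclassified_pct=self.unclassified_pct,
        )
        return row


def _validate_hsv(hsv: np.ndarray) -> np.ndarray:
    arr = np.asarray(hsv)
    if arr.shape[-1] != 3:
        raise ValueError("last axis must hold (H, S, V)")
    a = arr.astype(np.int64)
    if (a < 0).any() or (a[..., 0] > 180).any() or (a[..., 1:] > 255).any():
        raise ValueError("HSV components outside the OpenCV scale")
    return a


def classify_image(hsv: np.ndarray, palette: ColorPalette) -> np.ndarray:
    """Classify every pixel; returns an object-dtype-free integer map.

    Returns an int array indexing ``palette color_names``; -1 marks
    unclassified pixels. First matching range in precedence order wins.
    """
    a = _validate_hsv(hsv)
    lo, hi = palette.bound_arrays()
    flat = a.reshape(-1, 3)
    out = np.full(flat.shape[0], -1, dtype=np.int64)
    names = palette.color_names
    name_idx = {n: i for i, n in enumerate(names)}
    for r, l, h in zip(palette.ranges, lo, hi):
        unset = out == -1
        if not unset.any():
            break
        hit = unset & np.all((flat >= l) & (flat <= h), axis=1)
        out[hit] = name_idx[r.name]
    return out.reshape(a.shape[:-1])


def classify_pixel(hsv: tuple[int, int, int], palette: ColorPalette) -> str:
    """Classify one (H, S, V) triple; returns a color name or "unclassified"."""
    code = classify_image(np.asarray(hsv).reshape(1, 1, 3), palette)[0, 0]
    return palette.color_names[code] if code >= 0 else UNCLASSIFIED


def drawn_mask(hsv: np.ndarray, palette: ColorPalette) -> np.ndarray:
    """True where the pixel is outside the white (blank canvas) range."""
    a = _validate_hsv(hsv)
    white = palette.ranges_for(WHITE)
    if not white:
        raise ValueError("palette has no white range")
    in_white = np.zeros(a.shape[:-1], dtype=bool)
    for r in white:
        l = np.asarray(r.lower)
        h = np.asarray(r.upper)
        in_white |= np.all((a >= l) & (a <= h), axis=-1)
    return ~in_white


def _color_counts(hsv: np.ndarray, palette: ColorPalette) -> dict[str, int]:
    codes = classify_image(hsv, palette)
    names = palette.color_names
    counts = {n: int((codes == i).sum()) for i, n in enumerate(names)}
    counts[UNCLASSIFIED] = int((codes == -1).sum())
    return counts


def color_percentages(
    hsv: np.ndarray, palette: ColorPalette
) -> dict[str, float]:
    """Share of classified drawn pixels per expressive color.

    White and unclassified pixels are excluded from numerator and
    denominator, so the seven shares sum to exactly 100 (the counts are
    reduced with rational arithmetic before conversion to float).
    """
    counts = _color_counts(hsv, palette)
    total = sum(counts.get(c, 0) for c in EXPRESSIVE_COLORS)
    if total == 0:
        raise BlankCanvasError("no classified non-white pixels: blank canvas")
    return {
        c: float(Fraction(100 * counts.get(c, 0), total)) for c in EXPRESSIVE_COLORS
    }


def prominent_color(pct: Mapping[str, float]) -> str:
    """Color with the maximal share; ties broken by fixed palette order."""
    best = None
    best_v = -1.0
    for c in EXPRESSIVE_COLORS:
        v = pct.get(c, 0.0)
        if v > best_v:
            best, best_v = c, v
    assert best is not None
    return best


def count_colors(pct: Mapping[str, float], min_share: float = 1.0) -> int:
    """Number of expressive colors with share strictly above ``min_share`` %."""
    return sum(1 for c in EXPRESSIVE_COLORS if pct.get(c, 0.0) > min_share)


def saturation_brightness(
    hsv: np.ndarray, mask: np.ndarray
) -> tuple[float, float]:
    """Mean S and V over masked (drawn) pixels, rescaled to 0-100."""
    a = _validate_hsv(hsv)
    m = np.asarray(mask, dtype=bool)
    if m.shape != a.shape[:-1]:
        raise ValueError("mask shape must match image shape")
    if not m.any():
        raise BlankCanvasError("empty mask: blank canvas")
    s = a[..., 1][m].mean() / 255.0 * 100.0
    v = a[..., 2][m].mean() / 255.0 * 100.0
    return float(s), float(v)


def color_fill(mask: np.ndarray) -> float:
    """Drawn pixels as a percentage of the canvas."""
    m = np.asarray(mask, dtype=bool)
    return float(100.0 * m.sum() / m.size)


def image_coverage(mask: np.ndarray, connectivity: int = 1) -> float:
    """Drawn area plus enclosed blank holes, as a percentage of the canvas.

    Holes are background regions unreachable from the canvas border;
    ``connectivity`` 1 (4-neighbour, default) or 2 (8-neighbour) sets the
    flood-fill adjacency.
    """
    m = np.asarray(mask, dtype=bool)
    if connectivity not in (1, 2):
        raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")
    structure = ndimage.generate_binary_structure(2, connectivity)
    filled = ndimage.binary_fill_holes(m, structure=structure)
    return float(100.0 * filled.sum() / m.size)


def extract_features(
    img: RasterImage,
    palette: ColorPalette | None = None,
    *,
    min_share: float = 1.0,
    connectivity: int = 1,
) -> FeatureVector:
    """Compute the full feature vector for one drawing.

    Raises BlankCanvasError for an all-white (or unclassifiable) canvas;
    such drawings are excluded from statistics, mirroring the removal of
    unreadable or blank submissions.
    """
    palette = palette or ColorPalette()
    hsv = rgb_to_hsv_opencv(img)
    mask = drawn_mask(hsv, palette)
    if not mask.any():
        raise BlankCanvasError(f"{img.source_id or 'image'}: blank canvas")
    pct = color_percentages(hsv, palette)
    counts = _color_counts(hsv, palette)
    drawn = int(mask.sum())
    sat, bright = saturation_brightness(hsv, mask)
    return FeatureVector(
        source_id=img.source_id,
        prominent_color=prominent_color(pct),
        color_pct=pct,
        n_colors=count_colors(pct, min_share),
        saturation_pct=sat,
        brightness_pct=bright,
        color_fill_pct=color_fill(mask),
        image_coverage_pct=image_coverage(mask, connectivity=connectivity),
        unclassified_pct=100.0 * counts[UNCLASSIFIED] / drawn,
    )
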