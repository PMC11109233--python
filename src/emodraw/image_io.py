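"""Raster-image I/O and HSV conversion on the OpenCV integer scale.

Drawings are 8-bit RGB rasters on a white canvas. All downstream color
ranges are stated on the OpenCV HSV convention: hue in 0-180 (degrees
halved so it fits one byte), saturation and value in 0-255. The
conversion here follows the standard hexcone formula with half-even
rounding, so classification thresholds behave identically to an
OpenCV-based pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "RasterImage",
    "ImageDecodeError",
    "load_image",
    "save_image",
    "rgb_to_hsv_opencv",
    "hsv_to_rgb_opencv",
]


class ImageDecodeError(ValueError):
    """Raised when a drawing file cannot be decoded."""


@dataclass
class RasterImage:
    """An 8-bit RGB drawing.

    Attributes
    ----------
    pixels : ndarray of shape (height, width, 3), dtype uint8
    source_id : opaque tag, typically ``{participant}_{emotion}``
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must have shape (height, width, 3)")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def load_image(path: str | Path, source_id: str | None = None) -> RasterImage:
    """Load a JPEG/PNG drawing as 8-bit RGB.

    Any alpha channel is composited over a white canvas, matching the
    blank-white-canvas convention of the drawing task.

    Raises
    ------
    ImageDecodeError
        If the file is missing, truncated or not a decodable image.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("RGBA", "LA", "PA") or (
                im.mode == "P" and "transparency" in im.info
            ):
                im = im.convert("RGBA")
                canvas = Image.new("RGBA", im.size, (255, 255, 255, 255))
                canvas.alpha_composite(im)
                im = canvas.convert("RGB")
            else:
                im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except (OSError, UnidentifiedImageError, SyntaxError) as exc:
        raise ImageDecodeError(f"cannot decode image file {path!s}: {exc}") from exc
    return RasterImage(arr, source_id if source_id is not None else path.stem)


def save_image(img: RasterImage, path: str | Path) -> None:
    """Write a drawing as lossless PNG."""
    Image.fromarray(img.pixels, mode="RGB").save(Path(path), format="PNG")


def rgb_to_hsv_opencv(rgb: np.ndarray | RasterImage) -> np.ndarray:
    """Convert 8-bit RGB to HSV on the OpenCV scale.

    Per pixel with channels scaled to [0, 1]: V' = max(R, G, B);
    S' = 0 if V' = 0 else (V' - min)/V'; hue in degrees by the hexcone
    formula. Output H = round(H°/2) in 0-180 (180 is kept at the red
    wraparound so near-360° hues stay in the upper red range),
    S = round(S'*255), V = round(V'*255).

    Parameters
    ----------
    rgb : (..., 3) uint8 array or RasterImage

    Returns
    -------
    (..., 3) uint8 array of (H, S, V)
    """
    if isinstance(rgb, RasterImage):
        rgb = rgb.pixels
    arr = np.asarray(rgb)
    if arr.shape[-1] != 3:
        raise ValueError("last axis must hold (R, G, B)")
    # integer numerators + one float division keep exact-half cases
    # (k + 1/2 is representable) so half-even rounding is bit-reproducible
    a = arr.astype(np.int64)
    r, g, b = a[..., 0], a[..., 1], a[..., 2]
    vmax = a.max(axis=-1)
    vmin = a.min(axis=-1)
    c = vmax - vmin
    safe_vmax = np.where(vmax > 0, vmax, 1)
    safe_c = np.where(c > 0, c, 1)
    s = np.where(vmax > 0, 255.0 * c / safe_vmax, 0.0)
    # half-degrees directly: H deg / 2 = 30 * hue fraction + sector offset
    hh_r = np.mod(30.0 * (g - b) / safe_c, 180.0)
    hh_g = 30.0 * (b - r) / safe_c + 60.0
    hh_b = 30.0 * (r - g) / safe_c + 120.0
    hh = np.where(vmax == r, hh_r, np.where(vmax == g, hh_g, hh_b))
    hh = np.where(c > 0, hh, 0.0)
    out = np.empty(arr.shape, dtype=np.uint8)
    out[..., 0] = np.rint(hh).astype(np.uint8)
    out[..., 1] = np.rint(s).astype(np.uint8)
    out[..., 2] = vmax.astype(np.uint8)
    return out


def hsv_to_rgb_opencv(hsv: np.ndarray) -> np.ndarray:
    """Inverse conversion: OpenCV-scaled HSV triples to 8-bit RGB.

    Used by the synthetic renderer to paint pixels that land inside a
    chosen HSV color range after the forward conversion. The round trip
    is exact up to the +/-1 integer rounding of each channel.
    """
    arr = np.asarray(hsv, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError("last axis must hold (H, S, V)")
    hdeg = arr[..., 0] * 2.0
    s = arr[..., 1] / 255.0
    v = arr[..., 2] / 255.0
    c = v * s
    hp = hdeg / 60.0
    x = c * (1.0 - np.abs(np.mod(hp, 2.0) - 1.0))
    z = np.zeros_like(c)
    sector = np.floor(np.mod(hp, 6.0)).astype(int)
    rgb_c = np.stack(
        [
            np.choose(sector, [c, x, z, z, x, c]),
            np.choose(sector, [x, c, c, x, z, z]),
            np.choose(sector, [z, z, x, c, c, x]),
        ],
        axis=-1,
    )
    m = (v - c)[..., None]
    return np.clip(np.rint((rgb_c + m) * 255.0), 0, 255).astype(np.uint8)
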