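"""The named HSV color ranges used to classify drawing pixels.

Eight color names over nine inclusive HSV boxes on the OpenCV scale
(red is split across the hue wraparound). The six chromatic hue
intervals partition 0-180: red 0-10, yellow 11-36, green 37-83,
blue 84-124, purple 125-145, red again 146-180. The achromatic boxes
(black, white, gray) are distinguished by saturation and value only.

Because the black box (V <= 70 at any saturation) overlaps the low-value
corner of every chromatic box, classification applies a fixed precedence:
black, white, gray, then the chromatic ranges. Dark ambiguous pixels are
therefore called black, which matches how a V <= 70/255 pixel reads to
the eye. Pixels falling in none of the boxes (e.g. S between the gray
and chromatic saturation cut-offs) are "unclassified".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

__all__ = [
    "ColorRange",
    "ColorPalette",
    "default_palette",
    "EXPRESSIVE_COLORS",
    "UNCLASSIFIED",
    "WHITE",
]

#: The seven expressive colors, in fixed precedence/tie-break order.
EXPRESSIVE_COLORS: tuple[str, ...] = (
    "red",
    "yellow",
    "green",
    "blue",
    "purple",
    "gray",
    "black",
)

WHITE = "white"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ColorRange:
    """One inclusive HSV box: lower <= (H, S, V) <= upper componentwise."""

    name: str
    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        for lo, hi, cap in zip(self.lower, self.upper, (180, 255, 255)):
            if not (0 <= lo <= hi <= cap):
                raise ValueError(
                    f"invalid bounds for {self.name!r}: {self.lower}..{self.upper}"
                )

    def contains(self, hsv: tuple[int, int, int]) -> bool:
        return all(lo <= x <= hi for x, lo, hi in zip(hsv, self.lower, self.upper))


# Default ranges on the OpenCV scale.  Order = evaluation precedence.
_DEFAULT_RANGES: tuple[ColorRange, ...] = (
    ColorRange("black", (0, 0, 0), (180, 255, 70)),
    ColorRange("white", (0, 0, 230), (180, 30, 255)),
    ColorRange("gray", (0, 0, 71), (180, 25, 229)),
    ColorRange("red", (0, 53, 46), (10, 255, 255)),
    ColorRange("red", (146, 53, 46), (180, 255, 255)),
    ColorRange("yellow", (11, 46, 53), (36, 255, 255)),
    ColorRange("green", (37, 46, 53), (83, 255, 255)),
    ColorRange("blue", (84, 53, 46), (124, 255, 255)),
    ColorRange("purple", (125, 53, 46), (145, 255, 255)),
)


@dataclass(frozen=True)
class ColorPalette:
    """An ordered set of ColorRanges; order is classification precedence."""

    ranges: tuple[ColorRange, ...] = _DEFAULT_RANGES

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("palette must contain at least one range")

    @property
    def color_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.ranges:
            if r.name not in seen:
                seen.append(r.name)
        return tuple(seen)

    def ranges_for(self, name: str) -> tuple[ColorRange, ...]:
        return tuple(r for r in self.ranges if r.name == name)

    # -- vectorised bound arrays used by the classifiers -----------------
    def bound_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([r.lower for r in self.ranges], dtype=np.int64)
        hi = np.array([r.upper for r in self.ranges], dtype=np.int64)
        return lo, hi

    # -- plain-text serialisation ----------------------------------------
    def to_table(self, path: str | Path) -> None:
        """Write the palette as a TSV: name, lower H S V, upper H S V."""
        lines = ["name\th_lo\ts_lo\tv_lo\th_hi\ts_hi\tv_hi"]
        for r in self.ranges:
            lines.append("\t".join([r.name, *map(str, r.lower), *map(str, r.upper)]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_table(cls, path: str | Path) -> "ColorPalette":
        text = Path(path).read_text().strip().splitlines()
        if not text or not text[0].startswith("name"):
            raise ValueError(f"not a palette table: {path!s}")
        ranges = []
        for line in text[1:]:
            name, *nums = line.split("\t")
            nums = [int(x) for x in nums]
            ranges.append(ColorRange(name, tuple(nums[:3]), tuple(nums[3:])))
        return cls(tuple(ranges))

    def content_hash(self) -> str:
        """Stable short hash for run logs."""
        import hashlib

        payload = ";".join(
            f"{r.name}:{r.lower}:{r.upper}" for r in self.ranges
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def default_palette() -> ColorPalette:
    """The palette the analysis ships with (the canonical OpenCV ranges)."""
    return ColorPalette()
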