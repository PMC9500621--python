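"""Axis-aligned pixel boxes and coordinate plumbing.

Boxes are integer rectangles on the raster grid with 0-based, *inclusive*
corners: ``x`` indexes columns (horizontal), ``y`` indexes rows (vertical),
origin at the top-left.  A box therefore covers
``(x_max - x_min + 1) * (y_max - y_min + 1)`` pixels, and two boxes that
merely touch at a corner still share one pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "Box",
    "ImageSize",
    "make_box",
    "box_area",
    "intersect",
    "enclose",
    "overlaps",
    "rescale_box",
]


@dataclass(frozen=True)
class ImageSize:
    """Width/height of a raster image in pixels."""

    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(
                f"image size must be at least 1x1, got {self.width}x{self.height}"
            )


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle with 0-based inclusive corner coordinates."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        for name in ("x_min", "y_min", "x_max", "y_max"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise TypeError(f"{name} must be an int, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if self.x_min > self.x_max:
            raise ValueError(f"x_min > x_max ({self.x_min} > {self.x_max})")
        if self.y_min > self.y_max:
            raise ValueError(f"y_min > y_max ({self.y_min} > {self.y_max})")

    @property
    def width(self) -> int:
        """Horizontal extent N in pixels (inclusive bounds, hence +1)."""
        return self.x_max - self.x_min + 1

    @property
    def height(self) -> int:
        """Vertical extent M in pixels."""
        return self.y_max - self.y_min + 1

    @property
    def area(self) -> int:
        return self.width * self.height

    def contains(self, other: "Box") -> bool:
        """True iff every pixel of ``other`` lies inside ``self``."""
        return (
            self.x_min <= other.x_min
            and self.y_min <= other.y_min
            and self.x_max >= other.x_max
            and self.y_max >= other.y_max
        )

    def within(self, size: ImageSize) -> bool:
        """True iff the box lies entirely inside a ``size`` frame."""
        return self.x_max < size.width and self.y_max < size.height


def make_box(x_min: int, y_min: int, x_max: int, y_max: int) -> Box:
    """Validate and build a :class:`Box` (errors name the offending field)."""
    return Box(x_min, y_min, x_max, y_max)


def box_area(b: Box) -> int:
    """Number of pixels covered by ``b`` (width x height, inclusive bounds)."""
    return b.area


def intersect(a: Box, b: Box) -> Box | None:
    """Maximal box contained in both inputs, or ``None`` if no pixel is shared."""
    x_min = max(a.x_min, b.x_min)
    y_min = max(a.y_min, b.y_min)
    x_max = min(a.x_max, b.x_max)
    y_max = min(a.y_max, b.y_max)
    if x_min > x_max or y_min > y_max:
        return None
    return Box(x_min, y_min, x_max, y_max)


def enclose(bs: Sequence[Box] | Iterable[Box]) -> Box:
    """Smallest box containing every input box (componentwise min/max)."""
    bs = list(bs)
    if not bs:
        raise ValueError("enclose() requires at least one box")
    return Box(
        min(b.x_min for b in bs),
        min(b.y_min for b in bs),
        max(b.x_max for b in bs),
        max(b.y_max for b in bs),
    )


def overlaps(a: Box, b: Box) -> bool:
    """True iff the boxes share at least one pixel (inclusive corners count)."""
    return intersect(a, b) is not None


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def rescale_box(b: Box, from_size: ImageSize, to_size: ImageSize) -> Box:
    """Map a box between image frames of different sizes.

    Corner coordinates are scaled by ``to/from`` per axis, rounded to the
    nearest integer (half away from zero) and clamped into the target frame.
    Used to carry detector outputs (model-input coordinates) back to the
    original image frame.
    """
    if not b.within(from_size):
        raise ValueError(
            f"box {b} does not fit inside source frame "
            f"{from_size.width}x{from_size.height}"
        )
    sx = to_size.width / from_size.width
    sy = to_size.height / from_size.height

    def clamp(v: int, upper: int) -> int:
        return max(0, min(v, upper))

    x_min = clamp(_round_half_away(b.x_min * sx), to_size.width - 1)
    x_max = clamp(_round_half_away(b.x_max * sx), to_size.width - 1)
    y_min = clamp(_round_half_away(b.y_min * sy), to_size.height - 1)
    y_max = clamp(_round_half_away(b.y_max * sy), to_size.height - 1)
    # Rounding can collapse but never reverse an ordered pair after clamping.
    return Box(x_min, y_min, x_max, y_max)
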