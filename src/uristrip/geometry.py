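"""Axis-aligned pixel rectangles.

Rectangles are 0-based and half-open: a ``Rect(x, y, w, h)`` covers columns
``x .. x+w-1`` and rows ``y .. y+h-1``.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import SpecificationError


@dataclass(frozen=True)
class Rect:
    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise SpecificationError(f"rectangle must have positive size, got {self}")

    @property
    def x1(self) -> int:
        """Exclusive right edge."""
        return self.x + self.w

    @property
    def y1(self) -> int:
        """Exclusive bottom edge."""
        return self.y + self.h

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        """(cx, cy) in pixel coordinates."""
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def slices(self) -> tuple[slice, slice]:
        """(row_slice, col_slice) for indexing a numpy image."""
        return (slice(self.y, self.y1), slice(self.x, self.x1))

    def contains(self, other: "Rect") -> bool:
        return (
            self.x <= other.x
            and self.y <= other.y
            and other.x1 <= self.x1
            and other.y1 <= self.y1
        )

    def overlaps(self, other: "Rect") -> bool:
        return not (
            other.x >= self.x1
            or other.x1 <= self.x
            or other.y >= self.y1
            or other.y1 <= self.y
        )

    def inner_half(self) -> "Rect":
        """Centered sub-rectangle with half the width and half the height."""
        w = max(1, self.w // 2)
        h = max(1, self.h // 2)
        return Rect(self.x + (self.w - w) // 2, self.y + (self.h - h) // 2, w, h)

    def shifted(self, dx: int, dy: int) -> "Rect":
        return Rect(self.x + dx, self.y + dy, self.w, self.h)

    def expanded(self, margin: int) -> "Rect":
        return Rect(self.x - margin, self.y - margin, self.w + 2 * margin, self.h + 2 * margin)
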