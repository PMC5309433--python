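"""Axis-aligned rectangular regions in image coordinates.

Coordinates are 0-based with ``x`` the column and ``y`` the row; a region is
the half-open box ``[x, x+w) x [y, y+h)``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, slots=True)
class Region:
    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError(f"region must have positive size, got {self.w}x{self.h}")

    @property
    def area(self) -> int:
        return self.w * self.h

    def within(self, width: int, height: int) -> bool:
        return 0 <= self.x and 0 <= self.y and self.x + self.w <= width and self.y + self.h <= height

    def iou(self, other: "Region") -> float:
        """Intersection-over-union with another region."""
        ix = max(0, min(self.x + self.w, other.x + other.w) - max(self.x, other.x))
        iy = max(0, min(self.y + self.h, other.y + other.h) - max(self.y, other.y))
        inter = ix * iy
        union = self.area + other.area - inter
        return inter / union if union else 0.0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x, self.y, self.w, self.h)


def check_region(region: Region, width: int, height: int) -> None:
    """Raise ``ValueError`` if ``region`` does not lie inside a W x H image."""
    if not region.within(width, height):
        raise ValueError(
            f"region {region.as_tuple()} outside {width}x{height} image bounds"
        )
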