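"""Axis-aligned rectangles and small geometric helpers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, pixel coordinates: x, y is the top-left corner."""

    x: float
    y: float
    w: float
    h: float

    @property
    def x1(self) -> float:
        return self.x + self.w

    @property
    def y1(self) -> float:
        return self.y + self.h

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x + self.w / 2.0, self.y + self.h / 2.0])

    @property
    def area(self) -> float:
        return self.w * self.h

    def contains_point(self, p, margin: float = 0.0) -> bool:
        return (self.x - margin <= p[0] <= self.x1 + margin
                and self.y - margin <= p[1] <= self.y1 + margin)

    def contains_rect(self, other: "Rect") -> bool:
        return (self.x <= other.x and self.y <= other.y
                and other.x1 <= self.x1 and other.y1 <= self.y1)

    def intersects(self, other: "Rect") -> bool:
        return intersection_area(self, other) > 0

    def union(self, other: "Rect") -> "Rect":
        x0 = min(self.x, other.x)
        y0 = min(self.y, other.y)
        return Rect(x0, y0, max(self.x1, other.x1) - x0, max(self.y1, other.y1) - y0)

    def clip_to(self, width: float, height: float) -> "Rect":
        x0 = min(max(self.x, 0.0), width)
        y0 = min(max(self.y, 0.0), height)
        x1 = min(max(self.x1, 0.0), width)
        y1 = min(max(self.y1, 0.0), height)
        return Rect(x0, y0, x1 - x0, y1 - y0)

    @classmethod
    def from_center(cls, center, w: float, h: float) -> "Rect":
        return cls(center[0] - w / 2.0, center[1] - h / 2.0, w, h)

    @classmethod
    def bounding(cls, points) -> "Rect":
        pts = np.asarray(points, float)
        x0, y0 = pts.min(axis=0)
        x1, y1 = pts.max(axis=0)
        return cls(x0, y0, x1 - x0, y1 - y0)


def intersection_area(r1: Rect, r2: Rect) -> float:
    w = min(r1.x1, r2.x1) - max(r1.x, r2.x)
    h = min(r1.y1, r2.y1) - max(r1.y, r2.y)
    return max(w, 0.0) * max(h, 0.0)


def point_in_polygon(point, polygon: np.ndarray) -> bool:
    """Crossing-number test: is ``point`` strictly inside the closed polygon."""
    x, y = float(point[0]), float(point[1])
    px = polygon[:, 0]
    py = polygon[:, 1]
    qx = np.roll(px, -1)
    qy = np.roll(py, -1)
    crosses = (py > y) != (qy > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_at = px + (y - py) * (qx - px) / (qy - py)
    return bool(np.count_nonzero(crosses & (x < x_at)) % 2)
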