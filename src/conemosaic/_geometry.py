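"""Planar geometry helpers for retinal regions.

All coordinates are in micrometres in a flat, retina-centred frame:
origin at the optic-nerve head, +y dorsal, +x nasal.  Flat-mount
curvature is ignored; every region is a subset of the plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Disk:
    """Circular region (cx, cy, radius), μm."""

    cx: float
    cy: float
    radius: float

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.cx - self.radius,
            self.cy - self.radius,
            self.cx + self.radius,
            self.cy + self.radius,
        )

    def contains(self, x, y):
        return (np.asarray(x) - self.cx) ** 2 + (np.asarray(y) - self.cy) ** 2 <= self.radius**2

    def edge_distance(self, x, y):
        """Distance from (x, y) to the region boundary (positive inside)."""
        r = np.hypot(np.asarray(x) - self.cx, np.asarray(y) - self.cy)
        return self.radius - r

    def sample_uniform(self, n: int, rng: np.random.Generator):
        r = self.radius * np.sqrt(rng.random(n))
        th = rng.random(n) * 2.0 * np.pi
        return self.cx + r * np.cos(th), self.cy + r * np.sin(th)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle [x0, x1] × [y0, y1], μm."""

    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def area(self) -> float:
        return float((self.x1 - self.x0) * (self.y1 - self.y0))

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0, self.x1, self.y1)

    def contains(self, x, y):
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)

    def edge_distance(self, x, y):
        x = np.asarray(x)
        y = np.asarray(y)
        return np.minimum.reduce([x - self.x0, self.x1 - x, y - self.y0, self.y1 - y])

    def sample_uniform(self, n: int, rng: np.random.Generator):
        return (
            self.x0 + rng.random(n) * (self.x1 - self.x0),
            self.y0 + rng.random(n) * (self.y1 - self.y0),
        )


def square(cx: float, cy: float, side: float) -> Rect:
    h = side / 2.0
    return Rect(cx - h, cy - h, cx + h, cy + h)
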