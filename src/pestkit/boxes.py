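"""Axis-aligned box geometry in continuous pixel coordinates.

Boxes live in image coordinates: origin at the top-left corner, x
increasing rightward, y increasing downward.  A box is the closed
rectangle ``[x1, x2] x [y1, y2]`` with area ``(x2 - x1) * (y2 - y1)``;
no +-1 pixel adjustment is applied anywhere.

Besides the usual intersection-over-union this module provides the
point-line machinery used by the PLDIoU loss: the line through two box
centers in ``alpha*x - beta*y + lam = 0`` form and the squared distance
from a point to that line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Box",
    "Point",
    "LineCoeffs",
    "normalize_box",
    "box_center",
    "min_enclosing_box",
    "iou",
    "line_through",
    "point_line_penalty",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle with ``x1 <= x2`` and ``y1 <= y2``."""

    x1: float
    y1: float
    x2: float
    y2: float

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    def shifted(self, dx: float, dy: float) -> "Box":
        return Box(self.x1 + dx, self.y1 + dy, self.x2 + dx, self.y2 + dy)

    def scaled(self, s: float) -> "Box":
        """Scale about the origin by ``s > 0``."""
        return Box(self.x1 * s, self.y1 * s, self.x2 * s, self.y2 * s)


@dataclass(frozen=True)
class Point:
    x: float
    y: float


@dataclass(frozen=True)
class LineCoeffs:
    """Line through two points, ``alpha*x - beta*y + lam = 0``.

    For a line through p and q: ``alpha = q.y - p.y``,
    ``beta = q.x - p.x``, ``lam = q.x*p.y - p.x*q.y``.  Coincident
    points give ``alpha = beta = 0`` (degenerate flag).
    """

    alpha: float
    beta: float
    lam: float

    @property
    def degenerate(self) -> bool:
        return self.alpha == 0.0 and self.beta == 0.0


def normalize_box(x1: float, y1: float, x2: float, y2: float) -> Box:
    """Build a Box from four corners, reordering so x1<=x2, y1<=y2.

    Raises ``ValueError`` on non-finite input.
    """
    vals = (x1, y1, x2, y2)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"box corners must be finite, got {vals}")
    return Box(min(x1, x2), min(y1, y2), max(x1, x2), max(y1, y2))


def box_center(b: Box) -> Point:
    return Point((b.x1 + b.x2) / 2.0, (b.y1 + b.y2) / 2.0)


def min_enclosing_box(c: Box, g: Box) -> Box:
    """Smallest axis-aligned box containing both inputs."""
    return Box(
        min(c.x1, g.x1),
        min(c.y1, g.y1),
        max(c.x2, g.x2),
        max(c.y2, g.y2),
    )


def intersection_area(c: Box, g: Box) -> float:
    iw = min(c.x2, g.x2) - max(c.x1, g.x1)
    ih = min(c.y2, g.y2) - max(c.y1, g.y1)
    return max(0.0, iw) * max(0.0, ih)


def iou(c: Box, g: Box) -> float:
    """Intersection over union of two boxes, in [0, 1].

    A pair with zero union area (two degenerate boxes) has IoU 0 by
    convention, keeping downstream losses finite.
    """
    inter = intersection_area(c, g)
    union = c.area + g.area - inter
    if union <= 0.0:
        return 0.0
    return inter / union


def line_through(p: Point, q: Point) -> LineCoeffs:
    """Coefficients of the line through two points.

    Coincident points return the degenerate line (0, 0, 0); callers
    treat the associated distance penalty as zero.
    """
    alpha = q.y - p.y
    beta = q.x - p.x
    if alpha == 0.0 and beta == 0.0:
        return LineCoeffs(0.0, 0.0, 0.0)
    lam = q.x * p.y - p.x * q.y
    return LineCoeffs(alpha, beta, lam)


def point_line_penalty(line: LineCoeffs, p: Point) -> float:
    """Squared distance from a point to a line, ``>= 0``.

    Evaluates ``(alpha*x - beta*y + lam)^2 / (alpha^2 + beta^2)``.
    A degenerate line contributes zero by convention.
    """
    if line.degenerate:
        return 0.0
    num = line.alpha * p.x - line.beta * p.y + line.lam
    den = line.alpha * line.alpha + line.beta * line.beta
    return (num * num) / den
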