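"""Planar angle primitives for landmark photogrammetry.

All computations live in a canonical right-handed frame: ``y`` increases
cranially (up), ``x`` increases toward the subject's anterior in sagittal
views and toward the subject's anatomical left in frontal/back views.
Image pixel coordinates (y down) are converted to this frame at the I/O
boundary, never here.

Angles are returned in degrees at full floating-point precision; rounding
is a presentation concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class InvalidGeometryError(ValueError):
    """A geometric construction is degenerate (e.g. coincident landmarks)."""


@dataclass(frozen=True)
class Point2D:
    """A landmark position in the canonical (y-up) frame, in pixels."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidGeometryError(f"non-finite coordinates ({self.x}, {self.y})")


@dataclass(frozen=True)
class Line2D:
    """An undirected (or, where stated, p->q directed) line through two points."""

    p: Point2D
    q: Point2D
    label: str = ""

    def __post_init__(self) -> None:
        if self.p.x == self.q.x and self.p.y == self.q.y:
            name = f" ({self.label})" if self.label else ""
            raise InvalidGeometryError(
                f"degenerate line{name}: both points at ({self.p.x}, {self.p.y})"
            )

    @property
    def direction(self) -> tuple[float, float]:
        return (self.q.x - self.p.x, self.q.y - self.p.y)


@dataclass(frozen=True)
class FrameConvention:
    """Orientation of the canonical frame.

    ``anterior_sign`` is +1 when the subject's anterior points along +x
    (the default after I/O normalization) and -1 otherwise. ``y`` always
    increases cranially.
    """

    anterior_sign: int = 1

    def __post_init__(self) -> None:
        if self.anterior_sign not in (-1, 1):
            raise ValueError("anterior_sign must be +1 or -1")


def _require_distinct(a: Point2D, b: Point2D, what: str = "segment") -> None:
    if a.x == b.x and a.y == b.y:
        raise InvalidGeometryError(f"degenerate {what}: endpoints coincide at ({a.x}, {a.y})")


def angle_between(a: Line2D, b: Line2D, oriented: bool = False) -> float:
    """Angle in degrees between two lines (or two directed segments).

    Unoriented mode treats both arguments as undirected lines and returns a
    value in [0, 90]. Oriented mode takes each line's direction as p->q and
    returns the angle between the two direction vectors, in [0, 180].
    """
    ux, uy = a.direction
    vx, vy = b.direction
    dot = ux * vx + uy * vy
    cross = ux * vy - uy * vx
    theta = math.degrees(math.atan2(abs(cross), dot))  # [0, 180]
    if oriented:
        return theta
    return theta if theta <= 90.0 else 180.0 - theta


def angle_to_vertical(
    base: Point2D,
    tip: Point2D,
    signed: bool = False,
    frame: FrameConvention = FrameConvention(),
) -> float:
    """Angle in degrees between the segment base->tip and the vertical.

    Unsigned: fold of the segment onto the vertical axis, in [0, 90].
    Signed: positive when the tip deviates anteriorly from the vertical
    line through the base (gravity-line convention), in (-90, 90) for a
    cranially directed segment.
    """
    _require_distinct(base, tip)
    dx = tip.x - base.x
    dy = tip.y - base.y
    if signed:
        return math.degrees(math.atan2(frame.anterior_sign * dx, dy))
    return math.degrees(math.atan2(abs(dx), abs(dy)))


def angle_to_horizontal(a: Point2D, b: Point2D) -> float:
    """Unsigned elevation angle in degrees of segment a-b, in [0, 90]."""
    _require_distinct(a, b)
    return math.degrees(math.atan2(abs(b.y - a.y), abs(b.x - a.x)))


def rotate_about(p: Point2D, center: Point2D, degrees_ccw: float) -> Point2D:
    """Rotate a point about a center, counter-clockwise in the y-up frame."""
    rad = math.radians(degrees_ccw)
    c, s = math.cos(rad), math.sin(rad)
    dx, dy = p.x - center.x, p.y - center.y
    return Point2D(center.x + c * dx - s * dy, center.y + s * dx + c * dy)
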