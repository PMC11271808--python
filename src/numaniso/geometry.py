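"""Planar geometry in a fixation-centered frame.

All coordinates are in degrees of visual angle with the fixation point at
the origin, +x rightward and +y upward.  Every base disc carries a pair of
concentric elliptical interference zones scaled by its eccentricity: one
elongated along the fixation-disc axis (radial) and the same ellipse
rotated 90 degrees (tangential).  Orientations are stored modulo pi since
an ellipse is invariant under 180-degree rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "Point",
    "EllipseZone",
    "DegenerateZoneError",
    "eccentricity",
    "make_zones",
    "point_in_ellipse",
    "ellipses_overlap",
    "in_zone_overlap",
    "ELLIPSE_VERTICES",
]

#: Vertex count of the convex-polygon approximation used for overlap tests.
ELLIPSE_VERTICES = 64

_TWO_PI = 2.0 * math.pi


class DegenerateZoneError(ValueError):
    """Raised when a zone is requested for a point at zero eccentricity."""


@dataclass(frozen=True)
class Point:
    """A location in the visual field (degrees, fixation at origin)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")


def eccentricity(p: Point) -> float:
    """Euclidean distance of ``p`` from fixation, in degrees."""
    return math.hypot(p.x, p.y)


def polar_angle(p: Point) -> float:
    """Angle of the fixation-to-``p`` direction, radians in [0, 2*pi)."""
    return math.atan2(p.y, p.x) % _TWO_PI


@dataclass(frozen=True)
class EllipseZone:
    """An oriented elliptical interference zone.

    ``orientation`` is the direction of the major axis, counterclockwise
    from +x, stored modulo pi.
    """

    center: Point
    semi_major: float
    semi_minor: float
    orientation: float
    kind: Literal["radial", "tangential"]

    def __post_init__(self) -> None:
        if not self.semi_major >= self.semi_minor > 0:
            raise ValueError(
                f"require semi_major >= semi_minor > 0, got "
                f"({self.semi_major}, {self.semi_minor})"
            )
        if self.kind not in ("radial", "tangential"):
            raise ValueError(f"unknown zone kind {self.kind!r}")
        object.__setattr__(self, "orientation", self.orientation % math.pi)

    @property
    def area(self) -> float:
        return math.pi * self.semi_major * self.semi_minor

    def polygon(self, n_vertices: int = ELLIPSE_VERTICES) -> Polygon:
        """Convex inscribed polygon approximating the ellipse."""
        t = np.linspace(0.0, _TWO_PI, n_vertices, endpoint=False)
        u = self.semi_major * np.cos(t)
        v = self.semi_minor * np.sin(t)
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        xs = self.center.x + c * u - s * v
        ys = self.center.y + s * u + c * v
        return Polygon(zip(xs, ys))

    def contains(self, p: Point, tol: float = 1e-12) -> bool:
        """True iff ``p`` lies inside or on the boundary (exact conic test)."""
        dx = p.x - self.center.x
        dy = p.y - self.center.y
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (u / self.semi_major) ** 2 + (v / self.semi_minor) ** 2 <= 1.0 + tol


def make_zones(
    center: Point,
    major_factor: float = 0.25,
    minor_factor: float = 0.1,
) -> tuple[EllipseZone, EllipseZone]:
    """Build the (radial, tangential) zone pair for a base disc.

    The factors are FULL axis lengths as fractions of eccentricity, so the
    semi-axes are half of ``factor * eccentricity``.  The radial zone's
    major axis points along the fixation-center direction; the tangential
    zone is the same ellipse rotated 90 degrees.
    """
    if not 0 < minor_factor <= major_factor:
        raise ValueError("require 0 < minor_factor <= major_factor")
    ecc = eccentricity(center)
    if ecc <= 0.0:
        raise DegenerateZoneError("cannot scale a zone at zero eccentricity")
    a = major_factor * ecc / 2.0
    b = minor_factor * ecc / 2.0
    theta = polar_angle(center)
    radial = EllipseZone(center, a, b, theta, "radial")
    tangential = EllipseZone(center, a, b, theta + math.pi / 2.0, "tangential")
    return radial, tangential


def point_in_ellipse(p: Point, z: EllipseZone) -> bool:
    """True iff ``p`` is inside or on the boundary of ``z``."""
    return z.contains(p)


def ellipse_bbox_halfwidths(z: EllipseZone) -> tuple[float, float]:
    """Half-width and half-height of the ellipse's axis-aligned bounding box."""
    c, s = math.cos(z.orientation), math.sin(z.orientation)
    hw = math.hypot(z.semi_major * c, z.semi_minor * s)
    hh = math.hypot(z.semi_major * s, z.semi_minor * c)
    return hw, hh


def ellipses_overlap(z1: EllipseZone, z2: EllipseZone) -> bool:
    """True iff the two elliptical regions intersect.

    Cheap separation / inclusion bounds first, then the 64-gon
    approximation via shapely for the ambiguous band.
    """
    d = math.hypot(z2.center.x - z1.center.x, z2.center.y - z1.center.y)
    if d > z1.semi_major + z2.semi_major:
        return False
    if d <= z1.semi_minor + z2.semi_minor:
        return True
    return z1.polygon().intersects(z2.polygon())


def in_zone_overlap(p: Point, zr: EllipseZone, zt: EllipseZone) -> bool:
    """True iff ``p`` lies in the central lens shared by a disc's two zones.

    Both zones must be concentric (they belong to the same base disc).
    """
    if (
        abs(zr.center.x - zt.center.x) > 1e-9
        or abs(zr.center.y - zt.center.y) > 1e-9
    ):
        raise ValueError("zones must share the same center")
    return zr.contains(p) and zt.contains(p)
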