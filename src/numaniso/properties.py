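"""Summary statistics used to match radial and tangential displays.

Five covariates: mean eccentricity, mean nearest-neighbor spacing, convex
hull area of the disc centers, occupancy area (union of fixed-radius disks
around the centers) and density (numerosity per unit hull area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .generator import Display

__all__ = [
    "PropertyVector",
    "PROPERTY_NAMES",
    "mean_eccentricity",
    "mean_spacing",
    "mean_pairwise_spacing",
    "convex_hull_area",
    "occupancy_area",
    "density",
    "compute_properties",
]

PROPERTY_NAMES = (
    "mean_eccentricity",
    "mean_spacing",
    "convex_hull_area",
    "occupancy_area",
    "density",
)

#: Defaults for the occupancy estimate; the radius is a package choice and
#: must be reported alongside any occupancy figure.
DEFAULT_OCC_RADIUS = 1.0
DEFAULT_GRID_STEP = 0.02


@dataclass(frozen=True)
class PropertyVector:
    mean_eccentricity: float
    mean_spacing: float
    convex_hull_area: float
    occupancy_area: float
    density: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PROPERTY_NAMES])


def _centers(d: Display | np.ndarray) -> np.ndarray:
    pts = d.centers() if isinstance(d, Display) else np.asarray(d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of centers")
    return pts


def mean_eccentricity(d: Display | np.ndarray) -> float:
    """Mean distance of disc centers from fixation (degrees)."""
    pts = _centers(d)
    if len(pts) == 0:
        raise ValueError("empty display")
    return float(np.mean(np.hypot(pts[:, 0], pts[:, 1])))


def mean_spacing(d: Display | np.ndarray) -> float:
    """Mean nearest-neighbor center distance (degrees)."""
    pts = _centers(d)
    if len(pts) < 2:
        raise ValueError("spacing needs at least two discs")
    dist, _ = cKDTree(pts).query(pts, k=2)
    return float(np.mean(dist[:, 1]))


def mean_pairwise_spacing(d: Display | np.ndarray) -> float:
    """Mean over ALL center pairs; secondary spacing variant."""
    pts = _centers(d)
    if len(pts) < 2:
        raise ValueError("spacing needs at least two discs")
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    iu = np.triu_indices(len(pts), k=1)
    return float(np.mean(dist[iu]))


def convex_hull_area(d: Display | np.ndarray) -> float:
    """Area of the convex hull of disc centers; 0 for degenerate sets."""
    pts = _centers(d)
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is the area
    except QhullError:
        return 0.0  # collinear


def occupancy_area(
    d: Display | np.ndarray,
    occ_radius: float = DEFAULT_OCC_RADIUS,
    grid_step: float = DEFAULT_GRID_STEP,
) -> float:
    """Area of the union of disks of ``occ_radius`` around the centers.

    Estimated by rasterizing a grid at ``grid_step`` over the padded
    bounding box and counting cells whose center lies within
    ``occ_radius`` of any disc center.
    """
    if occ_radius <= 0:
        raise ValueError("occ_radius must be positive")
    pts = _centers(d)
    if len(pts) == 0:
        return 0.0
    lo = pts.min(axis=0) - occ_radius - grid_step
    hi = pts.max(axis=0) + occ_radius + grid_step
    xs = np.arange(lo[0], hi[0], grid_step)
    ys = np.arange(lo[1], hi[1], grid_step)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    dist, _ = cKDTree(pts).query(grid, k=1)
    return float(np.count_nonzero(dist <= occ_radius) * grid_step**2)


def density(d: Display | np.ndarray) -> float:
    """Numerosity per unit convex-hull area (items per squared degree)."""
    pts = _centers(d)
    hull = convex_hull_area(pts)
    if hull <= 0:
        raise ValueError("density undefined for a degenerate hull")
    return float(len(pts) / hull)


def compute_properties(
    d: Display | np.ndarray,
    occ_radius: float = DEFAULT_OCC_RADIUS,
    grid_step: float = DEFAULT_GRID_STEP,
) -> PropertyVector:
    return PropertyVector(
        mean_eccentricity=mean_eccentricity(d),
        mean_spacing=mean_spacing(d),
        convex_hull_area=convex_hull_area(d),
        occupancy_area=occupancy_area(d, occ_radius, grid_step),
        density=density(d),
    )
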