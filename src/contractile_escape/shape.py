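"""Cell shape index, elongation/orientation and boundary roughness.

Proxies for tissue surface tension: boundary cells of aggregates with a high
surface tension are tangentially elongated and the aggregate contour is
smooth, so we measure (i) the dimensionless shape index p0 = P0 / sqrt(A0)
(isoperimetric minimum 2*sqrt(pi) ~ 3.545 for a circle, larger for elongated
cells), (ii) the aspect ratio and major-axis orientation from the region's
second moments, (iii) the alignment of the major axis with the local tangent
direction around the aggregate centre, and (iv) the radial roughness of the
aggregate contour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "CellOutline",
    "ShapeResult",
    "shape_index",
    "elongation_orientation",
    "tangential_alignment",
    "boundary_roughness",
    "analyze_outline",
]

P0_MIN = 2.0 * math.sqrt(math.pi)  # isoperimetric lower bound (circle)


@dataclass
class CellOutline:
    """Ordered simple polygon (um), implicitly closed."""

    vertices: np.ndarray  # (n, 2)
    cell_id: str = "cell"
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("outline needs >= 3 (x, y) vertices")
        # drop a duplicated closing vertex
        if np.allclose(self.vertices[0], self.vertices[-1]) and len(self.vertices) > 3:
            self.vertices = self.vertices[:-1]
        if not Polygon(self.vertices).is_simple:
            raise ValueError("outline must be a simple (non-self-intersecting) polygon")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class ShapeResult:
    cell_id: str
    frame_id: int
    p0: float
    perimeter: float  # um
    area: float  # um^2
    aspect_ratio: float
    orientation: float  # rad, (-pi/2, pi/2]
    orientation_stable: bool
    tangential_alignment: float | None = None


def shape_index(outline: CellOutline) -> float:
    """Shape index p0 = perimeter / sqrt(area); 2*sqrt(pi) for a circle."""
    poly = outline.polygon
    area = poly.area
    if area <= 0:
        raise ValueError("degenerate polygon (zero area)")
    return poly.length / math.sqrt(area)


def _region_moments(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and central second-moment (covariance) matrix of the polygon
    interior, from the exact closed-form vertex sums."""
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    A = cross.sum() / 2.0
    if abs(A) < 1e-300:
        raise ValueError("degenerate polygon (zero area)")
    cx = ((x + xn) * cross).sum() / (6.0 * A)
    cy = ((y + yn) * cross).sum() / (6.0 * A)
    # second moments about the origin
    sxx = ((x**2 + x * xn + xn**2) * cross).sum() / (12.0 * A)
    syy = ((y**2 + y * yn + yn**2) * cross).sum() / (12.0 * A)
    sxy = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum() / (24.0 * A)
    cov = np.array([[sxx - cx**2, sxy - cx * cy], [sxy - cx * cy, syy - cy**2]])
    return np.array([cx, cy]), cov


def elongation_orientation(
    outline: CellOutline, stability_ratio: float = 1.05
) -> tuple[float, float, bool]:
    """Aspect ratio sqrt(l1/l2) >= 1 and major-axis angle in (-pi/2, pi/2].

    Returns (aspect_ratio, orientation, stable); ``stable`` is False when the
    moment eigenvalue ratio is below ``stability_ratio`` (near-isotropic shape,
    orientation numerically meaningless).
    """
    _, cov = _region_moments(outline.vertices)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    l2, l1 = max(evals[0], 0.0), max(evals[1], 1e-300)
    aspect = math.sqrt(l1 / max(l2, 1e-300))
    major = evecs[:, 1]
    theta = math.atan2(major[1], major[0])
    if theta <= -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi
    stable = (l1 / max(l2, 1e-300)) >= stability_ratio
    return aspect, theta, stable


def tangential_alignment(
    outline: CellOutline, spheroid_center: tuple[float, float]
) -> tuple[float, bool]:
    """cos 2(theta_major - theta_tangent): +1 tangential, -1 radial, 0 at 45 deg.

    The tangent direction is perpendicular to the radius from the aggregate
    centre to the cell centroid.  Returns (score, stable); unstable when the
    cell is near-isotropic.
    """
    centroid, _ = _region_moments(outline.vertices)
    r = centroid - np.asarray(spheroid_center, dtype=float)
    if np.hypot(*r) < 1e-12:
        raise ValueError("cell centroid coincides with the spheroid centre")
    aspect, theta, stable = elongation_orientation(outline)
    theta_radial = math.atan2(r[1], r[0])
    theta_tangent = theta_radial + math.pi / 2.0
    score = math.cos(2.0 * (theta - theta_tangent))
    return score, stable and aspect >= 1.05


def boundary_roughness(
    contour: CellOutline | np.ndarray,
    center: tuple[float, float],
    n_angles: int = 360,
) -> float:
    """Radial roughness std(r(theta)) / mean(r(theta)) of an aggregate contour.

    The radial function is sampled along ``n_angles`` uniform rays from
    ``center``.  If the contour is not star-shaped about the centre (some ray
    crosses the boundary more than once), the metric falls back to
    perimeter / convex-hull-perimeter - 1, which is 0 for convex contours.
    """
    outline = contour if isinstance(contour, CellOutline) else CellOutline(np.asarray(contour))
    poly = outline.polygon
    c = Point(center)
    if not poly.contains(c):
        raise ValueError("center must lie inside the contour")

    reach = 2.0 * max(np.hypot(*(outline.vertices - np.asarray(center)).T))
    radii = np.empty(n_angles)
    star = True
    boundary = poly.exterior
    for k, theta in enumerate(np.linspace(0, 2 * math.pi, n_angles, endpoint=False)):
        ray = LineString(
            [center, (center[0] + reach * math.cos(theta), center[1] + reach * math.sin(theta))]
        )
        hit = ray.intersection(boundary)
        if hit.is_empty:
            star = False
            break
        if hit.geom_type == "Point":
            radii[k] = c.distance(hit)
        elif hit.geom_type == "MultiPoint" and len(hit.geoms) == 1:
            radii[k] = c.distance(hit.geoms[0])
        else:
            star = False
            break
    if star:
        return float(np.std(radii) / np.mean(radii))
    return float(poly.length / poly.convex_hull.exterior.length - 1.0)


def analyze_outline(
    outline: CellOutline, spheroid_center: tuple[float, float] | None = None
) -> ShapeResult:
    """All per-cell shape metrics in one record."""
    poly = outline.polygon
    aspect, theta, stable = elongation_orientation(outline)
    align = None
    if spheroid_center is not None:
        align, _ = tangential_alignment(outline, spheroid_center)
    return ShapeResult(
        cell_id=outline.cell_id,
        frame_id=outline.frame_id,
        p0=shape_index(outline),
        perimeter=poly.length,
        area=poly.area,
        aspect_ratio=aspect,
        orientation=theta,
        orientation_stable=stable,
        tangential_alignment=align,
    )
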