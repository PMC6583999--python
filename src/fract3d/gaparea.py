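"""Total gap area in a standardized landmark-defined projection.

The metric summarizes the *whole* fracture in one number: every interior
fracture line has two displaced copies (one per fragment); projected
orthographically onto the landmark plane they bound a ribbon, and the total
gap area is the area of the union of all ribbons (mm^2) — overlapping
ribbons at line junctions are counted once.

The view plane is defined by three bony landmarks (anterior inferior iliac
spine, inferolateral foramen point, superior ramus prominence) and oriented
away from the pelvic midline, giving a reproducible lateral view of the
acetabulum.  Because the projection is along the view direction, a pure
step-off (displacement along the articular normal viewed face-on) projects
to zero ribbon width: this is deliberately a *gap* metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .config import DEFAULT
from .geometry import Plane, plane_from_points, as_point
from .io import LandmarkSet

log = logging.getLogger(__name__)


@dataclass
class StandardView:
    """Orthographic view onto the landmark plane, looking along ``direction``."""

    plane: Plane
    direction: np.ndarray  # unit, oriented from the midline toward the joint
    basis: np.ndarray      # (2, 3) in-plane orthonormal basis

    def project(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - self.plane.point) @ self.basis.T


def standard_view(landmarks: LandmarkSet, midline_hint) -> StandardView:
    """Build the standardized view from the three required landmarks.

    The plane normal is flipped so it points from ``midline_hint`` (any
    point near the body midline) toward the landmarks, i.e. laterally.
    """
    p1, p2, p3 = landmarks.require_view_landmarks()
    plane = plane_from_points(p1, p2, p3)
    centroid = (p1 + p2 + p3) / 3.0
    n = plane.normal.copy()
    if np.dot(n, centroid - as_point(midline_hint)) < 0:
        n = -n
    plane = Plane(point=centroid, normal=n)
    u = p2 - p1
    u = u - np.dot(u, n) * n
    u = u / np.linalg.norm(u)
    v = np.cross(n, u)
    return StandardView(plane=plane, direction=n, basis=np.stack([u, v]))


def _ribbon_polygon(a2: np.ndarray, b2: np.ndarray):
    """Planar ribbon between two projected copies of one line (may be invalid)."""
    coords = np.vstack([a2, b2[::-1]])
    poly = Polygon(coords)
    if not poly.is_valid:
        poly = shapely.make_valid(poly)
    return poly


def _rasterize_quads(quads: np.ndarray, step: float) -> float:
    """Union area of quads by rasterization at ``step`` (fallback path)."""
    lo = quads.reshape(-1, 2).min(axis=0) - step
    hi = quads.reshape(-1, 2).max(axis=0) + step
    nx = max(1, int(np.ceil((hi[0] - lo[0]) / step)))
    ny = max(1, int(np.ceil((hi[1] - lo[1]) / step)))
    occ = np.zeros((nx, ny), dtype=bool)
    xs = lo[0] + (np.arange(nx) + 0.5) * step
    ys = lo[1] + (np.arange(ny) + 0.5) * step
    for quad in quads:
        qlo = quad.min(axis=0)
        qhi = quad.max(axis=0)
        i0, i1 = np.searchsorted(xs, (qlo[0], qhi[0]))
        j0, j1 = np.searchsorted(ys, (qlo[1], qhi[1]))
        if i0 >= i1 or j0 >= j1:
            continue
        gx, gy = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel()], axis=-1)
        inside = np.zeros(len(pts), dtype=bool)
        for tri in (quad[[0, 1, 2]], quad[[0, 2, 3]]):
            e = np.roll(tri, -1, axis=0) - tri
            w = pts[:, None, :] - tri[None, :, :]
            cr = e[None, :, 0] * w[:, :, 1] - e[None, :, 1] * w[:, :, 0]
            inside |= (cr >= 0).all(axis=1) | (cr <= 0).all(axis=1)
        occ[i0:i1, j0:j1] |= inside.reshape(i1 - i0, j1 - j0)
    return float(occ.sum()) * step * step


def ribbon_polygons(profiles, view: StandardView, include_peripheral: bool = False):
    """Projected gap ribbons, one polygon (possibly multi-part) per line."""
    polys = []
    for prof in profiles:
        if prof.line.adjacent_fragment_id is None and not include_peripheral:
            continue
        own = prof.displaced_points
        other = own - prof.displacement
        a2, b2 = view.project(own), view.project(other)
        if len(a2) < 2:
            continue
        polys.append(_ribbon_polygon(a2, b2))
    return polys


def total_gap_area(
    profiles,
    view: StandardView,
    raster_step: float = DEFAULT.raster_step,
    include_peripheral: bool = False,
) -> float:
    """Area (mm^2) of the union of all projected gap ribbons.

    Interior lines are deduplicated per fragment pair by the caller (see
    :func:`fract3d.metrics.dedupe_interior`); overlap between different
    lines' ribbons is counted once by the union.  If polygon cleaning fails
    the area is rasterized at ``raster_step`` instead (logged).
    """
    if raster_step <= 0:
        raise ValueError("raster_step must be positive")
    profiles = [
        p for p in profiles
        if include_peripheral or p.line.adjacent_fragment_id is not None
    ]
    if not profiles:
        return 0.0
    try:
        polys = ribbon_polygons(profiles, view, include_peripheral=include_peripheral)
        return float(unary_union(polys).area)
    except Exception:  # noqa: BLE001 - geometry degeneracies fall back to raster
        log.warning("polygon union failed; falling back to rasterization at %.2g mm",
                    raster_step)
        quads = []
        for prof in profiles:
            own = prof.displaced_points
            other = own - prof.displacement
            a2, b2 = view.project(own), view.project(other)
            for i in range(len(a2) - 1):
                quads.append([a2[i], a2[i + 1], b2[i + 1], b2[i]])
        return _rasterize_quads(np.asarray(quads), raster_step)
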