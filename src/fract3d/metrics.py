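"""Fracture lines, step-off/gap profiles and their summaries.

Workflow: with every fragment brought into its reduced pose, the articular
region is identified (band around a least-squares sphere fitted to the
intact template cup, or an explicit planar patch), fracture lines are the
boundary edges of each fragment's articular region that are *not* part of
the intact joint margin, and each line point is measured by exact
transform-based correspondence:

    d(p) = T_own(p) - T_adj(p)      interior line (inter-fragment)
    d(p) = T_own(p) - p             peripheral line (vs. reduced pose)

where ``T`` maps reduced-pose points to their displaced (pre- or post-
operative) positions.  The decomposition into step-off and gap uses the
articular normal of the *template* model at ``p`` — displaced-fragment
normals are exactly what the metric must not depend on.

A 2D-slice emulator reproduces the conventional single-slice CT reading:
displacement components are projected into the slice plane before
decomposition, so the emulated 2D values can never exceed their 3D
counterparts at any point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .config import DEFAULT, Config
from .geometry import RigidTransform, Plane, decompose_displacement
from .io import FragmentSet

log = logging.getLogger(__name__)

_AXES = {"axial": 2, "coronal": 1, "sagittal": 0}


# ---------------------------------------------------------------------------
# articular region models


def _algebraic_sphere_fit(pts: np.ndarray):
    """Least-squares sphere through points: linear in (centre, r^2 - |c|^2)."""
    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = np.einsum("ij,ij->i", pts, pts)
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = x[:3]
    r = float(np.sqrt(max(x[3] + c @ c, 0.0)))
    return c, r


@dataclass
class SphericalCupRegion:
    """Articular surface model: a band around a fitted sphere, concave side.

    ``normals`` point from the surface toward the cup centre — the outward
    direction of the concave articular cartilage surface.
    """

    center: np.ndarray
    radius: float
    band: float = DEFAULT.sphere_band

    @classmethod
    def fit(cls, template: trimesh.Trimesh, band: float = DEFAULT.sphere_band):
        """Robustly fit the articular sphere to the intact template.

        Iteratively re-fits on inliers whose surface normal faces the current
        centre estimate (the concave side), so the outer cortical table and
        any extra-articular bone drop out.
        """
        pts = np.asarray(template.vertices)
        nrm = np.asarray(template.vertex_normals)
        sel = np.ones(len(pts), dtype=bool)
        c, r = _algebraic_sphere_fit(pts)
        for tol in (8.0, 4.0, 2.0, band):
            to_c = c - pts
            dist_c = np.linalg.norm(to_c, axis=1)
            resid = np.abs(dist_c - r)
            toward = np.einsum("ij,ij->i", nrm, to_c) > 0.3 * dist_c
            sel = (resid < tol) & toward
            if sel.sum() < 10:
                raise ValueError("articular sphere fit failed: too few concave inliers")
            c, r = _algebraic_sphere_fit(pts[sel])
        return cls(center=np.asarray(c), radius=float(r), band=band)

    def select_faces(self, mesh: trimesh.Trimesh) -> np.ndarray:
        """Faces whose vertices lie in the band and that face the cup centre."""
        d = np.abs(np.linalg.norm(mesh.vertices - self.center, axis=1) - self.radius)
        vert_ok = d <= self.band
        face_ok = vert_ok[mesh.faces].all(axis=1)
        to_c = self.center - mesh.triangles_center
        cosang = np.einsum("ij,ij->i", mesh.face_normals, to_c) / np.maximum(
            np.linalg.norm(to_c, axis=1), 1e-12
        )
        return face_ok & (cosang > 0.3)

    def normals(self, pts) -> np.ndarray:
        to_c = self.center - np.atleast_2d(np.asarray(pts, dtype=float))
        return to_c / np.linalg.norm(to_c, axis=1, keepdims=True)


@dataclass
class PlanarPatchRegion:
    """Articular surface model for a flat facet: a band around a plane."""

    plane: Plane
    band: float = DEFAULT.sphere_band

    def select_faces(self, mesh: trimesh.Trimesh) -> np.ndarray:
        d = np.abs(self.plane.signed_distance(mesh.vertices))
        vert_ok = d <= self.band
        face_ok = vert_ok[mesh.faces].all(axis=1)
        cosang = mesh.face_normals @ self.plane.normal
        return face_ok & (cosang > 0.3)

    def normals(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return np.tile(self.plane.normal, (len(pts), 1))


# ---------------------------------------------------------------------------
# fracture lines


@dataclass
class FractureLine:
    """Ordered polyline along a fragment's articular edge (reduced pose, mm)."""

    points: np.ndarray
    fragment_id: str
    adjacent_fragment_id: Optional[str] = None
    articular: bool = True

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("a fracture line needs >= 2 points in 3D")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def spacing(self) -> float:
        return self.length / (len(self.points) - 1)


def resample_polyline(points: np.ndarray, step: float, closed: bool = False) -> np.ndarray:
    """Resample to uniform spacing <= ``step`` (arc-length interpolation)."""
    points = np.asarray(points, dtype=float)
    if closed:
        points = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return points[:1].copy()
    n = max(1, int(np.ceil(total / step)))
    si = np.linspace(0.0, total, n + 1)
    out = np.column_stack([np.interp(si, s, points[:, k]) for k in range(3)])
    return out[:-1] if closed else out


def _boundary_chains(mesh: trimesh.Trimesh, face_mask: np.ndarray):
    """Chains of vertex indices along the boundary of the selected face set.

    Returns ``(path, closed)`` tuples; junction vertices (degree > 2) split
    chains.
    """
    f = mesh.faces[face_mask]
    if len(f) == 0:
        return []
    e = np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if len(boundary) == 0:
        return []
    adj: dict = {}
    for a, b in boundary:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    unused = {tuple(sorted(ed)) for ed in boundary.tolist()}

    def walk(start, nxt):
        path = [start, nxt]
        unused.discard(tuple(sorted((start, nxt))))
        while True:
            cand = [
                v for v in adj[path[-1]]
                if tuple(sorted((path[-1], v))) in unused
            ]
            if len(cand) != 1 or len(adj[path[-1]]) > 2:
                break
            path.append(cand[0])
            unused.discard(tuple(sorted((path[-2], path[-1]))))
        return path

    chains = []
    # open chains / junctions first
    for v, nbrs in adj.items():
        if len(nbrs) == 2:
            continue
        for n in list(nbrs):
            if tuple(sorted((v, n))) in unused:
                chains.append((walk(v, n), False))
    # remaining pure loops
    while unused:
        a, b = next(iter(unused))
        path = walk(a, b)
        closed = path[0] == path[-1]
        if closed:
            path = path[:-1]
        chains.append((path, closed))
    return chains


def _chain_tangents(pts: np.ndarray) -> np.ndarray:
    t = np.gradient(pts, axis=0)
    return t / np.maximum(np.linalg.norm(t, axis=1, keepdims=True), 1e-12)


class _MarginFilter:
    """Identifies boundary points that belong to the intact joint margin.

    The intact template's own articular boundary (e.g. the acetabular rim)
    exists before any fracture; fragment boundary points that lie on it *and
    run along it* are margin, not fracture.  Fracture lines typically meet
    the margin roughly perpendicular, so a tangency test keeps their
    endpoints.
    """

    def __init__(self, template: trimesh.Trimesh, region, config: Config = DEFAULT):
        mask = region.select_faces(template)
        pts_list, tan_list = [], []
        for path, closed in _boundary_chains(template, mask):
            p = resample_polyline(template.vertices[path], config.resample_step,
                                  closed=closed)
            if len(p) < 2:
                continue
            pts_list.append(p)
            tan_list.append(_chain_tangents(p))
        if pts_list:
            self.points = np.vstack(pts_list)
            self.tangents = np.vstack(tan_list)
            self.tree = cKDTree(self.points)
        else:
            self.tree = None
        self.tol = config.rim_exclusion_tol

    def is_margin(self, pts: np.ndarray, tangents: np.ndarray) -> np.ndarray:
        if self.tree is None:
            return np.zeros(len(pts), dtype=bool)
        dist, idx = self.tree.query(pts, workers=-1)
        along = np.abs(np.einsum("ij,ij->i", tangents, self.tangents[idx]))
        return (dist < self.tol) & (along > np.cos(np.radians(45.0)))


def extract_fracture_lines(
    fragments: FragmentSet,
    region,
    template: trimesh.Trimesh,
    config: Config = DEFAULT,
):
    """Trace fracture lines along each fragment's articular edges (reduced pose).

    Every returned line is resampled at <= ``config.resample_step`` mm and
    carries the id of the adjacent fragment (nearest other fragment within
    ``config.adjacency_tol``) or ``None`` for a peripheral edge.  Interior
    lines appear once per fragment, i.e. twice per fragment pair; consumers
    that must count each pair once keep the copy owned by the smaller id.
    """
    margin = _MarginFilter(template, region, config)

    def surface_tree(mesh):
        # vertices alone under-resolve coarse meshes (a box has 8), so add a
        # uniform area-based surface sample for the adjacency distance test
        pts = [np.asarray(mesh.vertices)]
        n_extra = int(np.ceil(2.0 * mesh.area))
        if n_extra > len(mesh.vertices):
            extra, _ = trimesh.sample.sample_surface(mesh, n_extra, seed=config.seed)
            pts.append(np.asarray(extra))
        return cKDTree(np.vstack(pts))

    trees = {fid: surface_tree(m) for fid, m in fragments}
    lines = []
    for fid, mesh in fragments:
        mask = region.select_faces(mesh)
        if not mask.any():
            log.info("fragment %s has no articular region", fid)
            continue
        chains = _boundary_chains(mesh, mask)
        if not chains:
            log.info("fragment %s has no articular boundary", fid)
            continue
        for path, closed in chains:
            pts = resample_polyline(mesh.vertices[path], config.resample_step,
                                    closed=closed)
            if len(pts) < 2:
                continue
            keep = ~margin.is_margin(pts, _chain_tangents(pts))
            # adjacency per point: nearest other fragment within tolerance
            near_id = np.full(len(pts), -1)
            near_d = np.full(len(pts), np.inf)
            for k, (ofid, _) in enumerate(fragments):
                if ofid == fid:
                    continue
                d, _idx = trees[ofid].query(pts, workers=-1)
                better = d < near_d
                near_d[better] = d[better]
                near_id[better] = k
            near_id[near_d > config.adjacency_tol] = -1
            # split into maximal runs of (kept, same adjacent fragment)
            tag = np.where(keep, near_id, -2)  # -2: dropped margin point
            if closed and keep.all() and len(np.unique(tag)) == 1:
                runs = [np.arange(len(pts))]
            else:
                if closed:
                    # rotate so a boundary between runs is at position 0
                    change = np.nonzero(tag != np.roll(tag, 1))[0]
                    shift = change[0] if len(change) else 0
                    order = np.roll(np.arange(len(pts)), -shift)
                else:
                    order = np.arange(len(pts))
                runs, cur = [], [order[0]]
                for a, b in zip(order[:-1], order[1:]):
                    if tag[b] == tag[a]:
                        cur.append(b)
                    else:
                        runs.append(np.asarray(cur))
                        cur = [b]
                runs.append(np.asarray(cur))
            for run in runs:
                if len(run) < 2 or tag[run[0]] == -2:
                    continue
                adj = None if tag[run[0]] == -1 else fragments.fragment_ids[tag[run[0]]]
                lines.append(
                    FractureLine(
                        points=pts[run], fragment_id=fid,
                        adjacent_fragment_id=adj, articular=True,
                    )
                )
    return lines


# ---------------------------------------------------------------------------
# displacement profiles


@dataclass
class DisplacementProfile:
    """Per-point displacement along one fracture line."""

    line: FractureLine
    displacement: np.ndarray     # (n, 3) mm
    normals: np.ndarray          # (n, 3) template articular normals at the points
    step_off: np.ndarray         # (n,) mm, unsigned
    gap: np.ndarray              # (n,) mm
    signed_step_off: np.ndarray  # (n,) mm, + = proud along the articular normal
    displaced_points: np.ndarray  # (n, 3) own-fragment points in displaced pose

    def __post_init__(self):
        n = len(self.line.points)
        for arr in (self.displacement, self.normals, self.step_off, self.gap,
                    self.signed_step_off, self.displaced_points):
            if len(arr) != n:
                raise ValueError("profile arrays must match the line's point count")


def displacement_profile(
    line: FractureLine,
    pose_displaced: RigidTransform,
    pose_adjacent: Optional[RigidTransform],
    region,
) -> DisplacementProfile:
    """Measure one fracture line by exact transform-based correspondence.

    ``pose_displaced`` / ``pose_adjacent`` map reduced-pose points to the
    displaced state (the inverses of the virtual-reduction transforms).  For
    interior lines the displacement is the *relative* inter-fragment motion;
    for peripheral lines (no adjacent fragment) it is the motion w.r.t. the
    reduced pose itself.
    """
    if pose_displaced is None:
        raise ValueError("own-fragment pose is required")
    if line.adjacent_fragment_id is not None and pose_adjacent is None:
        raise ValueError(
            f"line on {line.fragment_id!r} is adjacent to "
            f"{line.adjacent_fragment_id!r} but no adjacent pose was given"
        )
    p = line.points
    own = pose_displaced.apply(p)
    other = pose_adjacent.apply(p) if line.adjacent_fragment_id is not None else p
    d = own - other
    n = region.normals(p)
    signed, gap = decompose_displacement(d, n, signed=True)
    return DisplacementProfile(
        line=line, displacement=d, normals=n,
        step_off=np.abs(signed), gap=gap, signed_step_off=signed,
        displaced_points=own,
    )


@dataclass
class MeasurementSummary:
    """Maximum and arc-length-weighted mean step-off and gap (mm)."""

    max_step_off: float
    mean_step_off: float
    max_gap: float
    mean_gap: float
    state: str = "pre"

    def __post_init__(self):
        if self.max_step_off < self.mean_step_off - 1e-9 or self.max_gap < self.mean_gap - 1e-9:
            raise ValueError("max must not be below mean")


def summarize(profiles, state: str = "pre") -> MeasurementSummary:
    """Pool profiles: max over every point, mean weighted by arc length."""
    profiles = list(profiles)
    if not profiles or sum(len(p.step_off) for p in profiles) == 0:
        raise ValueError("no profile points to summarize")
    step = np.concatenate([p.step_off for p in profiles])
    gap = np.concatenate([p.gap for p in profiles])
    w = np.concatenate([np.full(len(p.step_off), p.line.spacing) for p in profiles])
    w = w / w.sum()
    return MeasurementSummary(
        max_step_off=float(step.max()),
        mean_step_off=float(step @ w),
        max_gap=float(gap.max()),
        mean_gap=float(gap @ w),
        state=state,
    )


def dedupe_interior(profiles):
    """Keep one profile per unordered fragment pair (owner = smaller id)."""
    out = []
    for p in profiles:
        adj = p.line.adjacent_fragment_id
        if adj is not None and str(p.line.fragment_id) > str(adj):
            continue
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# 2D-slice emulation


def slice_2d_measurement(
    profiles,
    axis: str = "axial",
    slice_thickness: float = DEFAULT.slice_thickness,
):
    """Emulate maximum gap/step-off as read from a stack of 2D CT slices.

    The step and gap vectors of each line point are orthographically
    projected into the slice plane before being measured, then the maximum
    is taken over all slices.  Because a projection cannot lengthen a
    vector, the emulated 2D gap and step-off are <= their 3D counterparts at
    every single point.  Returns ``(max_gap_2d, max_step_off_2d)``.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    if slice_thickness <= 0:
        raise ValueError("slice thickness must be positive")
    profiles = list(profiles)
    pts = np.concatenate([p.displaced_points for p in profiles])
    step3 = np.concatenate([p.step_off for p in profiles])
    gap3 = np.concatenate([p.gap for p in profiles])
    nrm = np.concatenate([p.normals for p in profiles])
    disp = np.concatenate([p.displacement for p in profiles])
    k = _AXES[axis]

    # in-plane shrink factors of the normal and tangential unit directions
    n_inplane = np.sqrt(np.clip(1.0 - nrm[:, k] ** 2, 0.0, 1.0))
    dn = np.einsum("ij,ij->i", disp, nrm)
    tang = disp - dn[:, None] * nrm
    tnorm = np.linalg.norm(tang, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_inplane = np.where(
            tnorm > 1e-12,
            np.sqrt(np.clip(1.0 - (tang[:, k] / np.maximum(tnorm, 1e-12)) ** 2, 0.0, 1.0)),
            0.0,
        )
    step2 = step3 * n_inplane
    gap2 = gap3 * t_inplane

    coords = pts[:, k]
    lo = coords.min()
    idx = np.floor((coords - lo) / slice_thickness + 0.5).astype(int)
    if len(idx) == 0:
        log.warning("no fracture-line points intersect any %s slice", axis)
        return 0.0, 0.0
    max_gap = 0.0
    max_step = 0.0
    for s in np.unique(idx):
        in_slice = idx == s
        max_gap = max(max_gap, float(gap2[in_slice].max()))
        max_step = max(max_step, float(step2[in_slice].max()))
    return max_gap, max_step
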