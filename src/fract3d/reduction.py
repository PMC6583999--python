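"""Virtual anatomical reduction against the mirrored intact side.

The intact contralateral hemipelvis is reflected across the midsagittal
plane to produce a patient-specific template of the uninjured anatomy.
Each displaced fragment is then rigidly registered to that template
(point-to-plane ICP with trimmed correspondences); the recovered transform
*is* the virtual reduction.  A second registration matches the reduced
fragments into the postoperative model to recover the surgical result.

ICP notes
---------
* Correspondences are nearest neighbours in a dense, seeded surface sample
  of the target; the target sample's face normal provides the plane for the
  point-to-plane residual, which converges far faster than point-to-point
  on smooth articular surfaces.
* Fragments only cover part of the template, and their fracture (cut)
  surfaces have no counterpart on the intact anatomy, so correspondences
  beyond ``3 x median`` distance are trimmed each iteration.
* RMS is tracked over the trimmed set; if an update fails to improve it the
  previous pose is kept, so the reported RMS sequence is non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .config import DEFAULT, Config
from .geometry import Plane, RigidTransform, mirror_transform
from .io import FragmentSet

log = logging.getLogger(__name__)


@dataclass
class Registration:
    """Result of one rigid registration."""

    transform: RigidTransform
    rms: float
    iterations: int
    converged: bool


@dataclass
class ReductionResult:
    """Per-fragment virtual-reduction transforms (displaced -> reduced pose)."""

    transforms: dict            # fragment_id -> RigidTransform
    rms: dict                   # fragment_id -> float (mm)
    iterations: dict
    unreduced: list = field(default_factory=list)

    def displaced_pose(self, fragment_id) -> RigidTransform:
        """Reduced -> displaced transform (the measured displacement)."""
        return self.transforms[fragment_id].inverse()


def build_mirror_template(
    intact_mesh: trimesh.Trimesh, symmetry_plane: Plane
) -> trimesh.Trimesh:
    """Reflect the intact side across the (mid-sagittal) symmetry plane."""
    if len(intact_mesh.vertices) == 0:
        raise ValueError("intact mesh is empty")
    refl = mirror_transform(symmetry_plane)
    out = intact_mesh.copy()
    out.vertices = refl.apply(out.vertices)
    out.invert()  # reflection flips face orientation
    out.metadata["fragment_id"] = "mirror_template"
    return out


def symmetry_plane_from_landmarks(left_pts, right_pts) -> Plane:
    """Mid-sagittal plane from bilateral landmark pairs (midpoints + normal)."""
    left_pts = np.atleast_2d(np.asarray(left_pts, dtype=float))
    right_pts = np.atleast_2d(np.asarray(right_pts, dtype=float))
    mids = (left_pts + right_pts) / 2.0
    normal = (right_pts - left_pts).mean(axis=0)
    return Plane(point=mids.mean(axis=0), normal=normal)


class _TargetField:
    """Closest-point queries against a dense seeded surface sample."""

    def __init__(self, target: trimesh.Trimesh, n_samples: int, seed: int):
        pts, fidx = trimesh.sample.sample_surface(target, n_samples, seed=seed)
        self.points = np.asarray(pts)
        self.normals = np.asarray(target.face_normals[fidx])
        self.tree = cKDTree(self.points)

    def closest(self, query):
        dist, idx = self.tree.query(query, workers=-1)
        return dist, self.points[idx], self.normals[idx]


def _solve_point_to_plane(src, tgt, nrm, max_rot=0.2, max_trans=5.0, weights=None):
    """One linearized rigid update minimizing sum(((R s + t - q) . n)^2).

    The update is solved about the source centroid (better conditioning) and
    capped (``max_rot`` rad, ``max_trans`` mm) so far-from-aligned starts
    follow the closest-point field instead of taking wild Gauss-Newton jumps.
    """
    centroid = src.mean(axis=0)
    s = src - centroid
    r = np.einsum("ij,ij->i", src - tgt, nrm)
    A = np.hstack([np.cross(s, nrm), nrm])
    if weights is not None:
        sw = np.sqrt(weights)[:, None]
        A = A * sw
        r = r * sw[:, 0]
    x, *_ = np.linalg.lstsq(A, -r, rcond=None)
    w, t = x[:3], x[3:]
    theta = np.linalg.norm(w)
    if theta > max_rot:
        t = t * (max_rot / theta)
        w = w * (max_rot / theta)
        theta = max_rot
    tn = np.linalg.norm(t)
    if tn > max_trans:
        t = t * (max_trans / tn)
    if theta < 1e-14:
        R = np.eye(3)
    else:
        k = w / theta
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
    # rotation about the centroid, then translation
    return RigidTransform(rotation=R, translation=centroid - R @ centroid + t)


def icp_register(
    source_points,
    target: trimesh.Trimesh,
    init: Optional[RigidTransform] = None,
    max_iter: int = DEFAULT.icp_max_iter,
    tol: float = DEFAULT.reg_tol,
    trim: bool = True,
    target_samples: int = DEFAULT.icp_target_samples,
    seed: int = DEFAULT.seed,
    target_field: Optional[_TargetField] = None,
) -> Registration:
    """Point-to-plane ICP of a point cloud onto a target surface.

    Returns the rigid transform mapping the source points onto the target,
    with the RMS of the (trimmed) closest-point distances.  Non-convergence
    within ``max_iter`` is flagged, not raised.
    """
    src0 = np.atleast_2d(np.asarray(source_points, dtype=float))
    if len(src0) < 3:
        raise ValueError("ICP needs at least 3 source points")
    if np.linalg.matrix_rank(src0 - src0.mean(axis=0), tol=1e-9) < 2:
        raise ValueError("ICP source points are collinear")
    field_ = target_field or _TargetField(target, target_samples, seed)

    def run_phase(T_start, phase_trim, n_iter, patience=8):
        """Iterate from T_start, tracking the best pose by (trimmed) RMS."""
        T = T_start
        best_rms, best_T = np.inf, T_start
        total = 0
        stalled = 0
        for _ in range(n_iter):
            total += 1
            cur = T.apply(src0)
            dist, tgt, nrm = field_.closest(cur)
            if phase_trim:
                keep = dist <= max(3.0 * np.median(dist), 1.0)
            else:
                keep = np.ones(len(dist), dtype=bool)
            # point-to-plane residual: true surface mismatch, insensitive to
            # the discretization of the target sample
            resid = np.einsum("ij,ij->i", cur[keep] - tgt[keep], nrm[keep])
            rms = float(np.sqrt(np.mean(resid**2)))
            if rms < best_rms - tol:
                best_rms, best_T = rms, T
                stalled = 0
            else:
                best_rms = min(best_rms, rms)
                if rms <= best_rms + tol:
                    best_T = T if rms <= best_rms else best_T
                stalled += 1
                if stalled > patience:
                    break
            T = _solve_point_to_plane(cur[keep], tgt[keep], nrm[keep]).compose(T)
        return best_T, best_rms, total

    def polish(T_start, n_iter=10):
        """IRLS point-to-plane with Tukey weights: suppresses correspondences
        with no true counterpart (fracture surfaces, occluded edges)."""
        T = T_start
        best_rms, best_T = np.inf, T_start
        for _ in range(n_iter):
            cur = T.apply(src0)
            dist, tgt, nrm = field_.closest(cur)
            r = np.einsum("ij,ij->i", cur - tgt, nrm)
            scale = max(4.685 * 1.4826 * np.median(np.abs(r - np.median(r))), 0.05)
            u = np.clip(r / scale, -1.0, 1.0)
            w = (1.0 - u**2) ** 2
            inlier = np.abs(r) <= scale
            if inlier.sum() >= 6:
                rms = float(np.sqrt(np.mean(r[inlier] ** 2)))
            else:
                rms = float(np.sqrt(np.mean(r**2)))
            if rms < best_rms:
                best_rms, best_T = rms, T
            if w.sum() < 6:
                break
            T = _solve_point_to_plane(cur, tgt, nrm, weights=w).compose(T)
        return best_T, best_rms

    # phase 1: all correspondences, so sparse distinctive geometry (the
    # extra-articular bone) can steer the pose from a distant start
    T1, rms1, it1 = run_phase(init or RigidTransform.identity(), False, max_iter)
    if trim:
        # phase 2: trimmed refinement removes fracture-surface points that
        # have no counterpart on the intact template
        T2, _, it2 = run_phase(T1, True, max(10, max_iter // 2), patience=4)
        # phase 3: robust polish for the final fraction of a degree
        T3, rms3 = polish(T2)
    else:
        T3, rms3, it2 = T1, rms1, 0
    converged = it1 < max_iter
    return Registration(transform=T3, rms=rms3, iterations=it1 + it2, converged=converged)


def _sample_fragment(mesh: trimesh.Trimesh, n: int, seed: int) -> np.ndarray:
    pts, _ = trimesh.sample.sample_surface(mesh, n, seed=seed)
    return np.asarray(pts)


def reduce_fragments(
    fragments: FragmentSet,
    template: trimesh.Trimesh,
    config: Config = DEFAULT,
) -> ReductionResult:
    """Register every displaced fragment onto the mirror template.

    Fragments whose final RMS exceeds ``config.rms_max`` (template does not
    explain them: comminution, wrong bone, strong bilateral asymmetry) are
    flagged ``unreduced`` rather than reported as a silent bad fit.
    """
    field_ = _TargetField(template, config.icp_target_samples, config.seed)
    transforms, rms, iterations, unreduced = {}, {}, {}, []
    for fid, mesh in fragments:
        src = _sample_fragment(mesh, config.icp_samples, config.seed)
        reg = icp_register(
            src, template, init=RigidTransform.identity(),
            max_iter=config.icp_max_iter, tol=config.reg_tol,
            seed=config.seed, target_field=field_,
        )
        transforms[fid] = reg.transform
        rms[fid] = reg.rms
        iterations[fid] = reg.iterations
        if reg.rms > config.rms_max:
            unreduced.append(fid)
            log.warning("fragment %s flagged unreduced (RMS %.2f mm)", fid, reg.rms)
    return ReductionResult(
        transforms=transforms, rms=rms, iterations=iterations, unreduced=unreduced
    )


def match_pre_to_post(
    pre_fragments: FragmentSet,
    post_model: trimesh.Trimesh,
    reduction: ReductionResult,
    config: Config = DEFAULT,
) -> ReductionResult:
    """Locate each preoperative fragment inside the postoperative model.

    Initialized from the virtual-reduction transforms (the post pose is near
    the reduced pose); returns displaced(pre) -> post transforms.  Fragments
    that cannot be matched (missing in the post model) are flagged.
    """
    field_ = _TargetField(post_model, config.icp_target_samples, config.seed)
    transforms, rms, iterations, unmatched = {}, {}, {}, []
    for fid, mesh in pre_fragments:
        src = _sample_fragment(mesh, config.icp_samples, config.seed)
        reg = icp_register(
            src, post_model, init=reduction.transforms[fid],
            max_iter=config.icp_max_iter, tol=config.reg_tol,
            seed=config.seed, target_field=field_,
        )
        transforms[fid] = reg.transform
        rms[fid] = reg.rms
        iterations[fid] = reg.iterations
        if reg.rms > config.rms_max:
            unmatched.append(fid)
            log.warning("fragment %s flagged unmatched in post model (RMS %.2f mm)",
                        fid, reg.rms)
    return ReductionResult(
        transforms=transforms, rms=rms, iterations=iterations, unreduced=unmatched
    )
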