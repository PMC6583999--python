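"""Synthetic fractured-cup phantoms with exact ground truth.

The phantom emulates the geometry that drives an articular (acetabular)
fracture measurement: a hemispherical shell "cup" (articular radius 27 mm,
shell thickness 4 mm by default) fractured into 2-3 fragments by vertical
cut planes through the apex, each fragment displaced by a known rigid
transform.  A mirror-image intact cup on the contralateral side provides the
template for virtual reduction, and three landmarks on the rim plane define
the standardized projection view.

A perfectly hemispherical cup is rotationally symmetric about its own axis,
so a fragment's azimuthal position would be unrecoverable by surface
registration.  Real fragments carry extra-articular bone that pins this
degree of freedom; the phantom emulates that with small rectangular fins on
the outer shell (one per fragment, mirrored on the intact side).  The
articular surface itself stays an exact sphere, so analytic ground truth is
available at every fracture-line point:

    d(p) = T_own(p) - T_adj(p),   n(p) = (c - p) / ||c - p||

with ``T`` the applied displacement transforms and ``c`` the cup centre.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh

from .config import DEFAULT
from .geometry import Plane, RigidTransform, decompose_displacement
from .io import FragmentSet, LandmarkSet, VoxelVolume, REQUIRED_LANDMARKS

log = logging.getLogger(__name__)

#: truth sampling step along fracture lines (mm); far below any tolerance
TRUTH_STEP = 0.1


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the fractured-cup phantom (mm)."""

    cup_radius: float = 27.0        # articular (inner) radius
    shell_thickness: float = 4.0
    #: sector boundaries (deg); each boundary is a planar cut through the
    #: apex, so (0, 180) is one cut plane -> 2 fragments, (0, 120, 240) -> 3
    sector_azimuths_deg: tuple = (0.0, 180.0)
    #: per-fragment reduced->displaced transforms; None = draw from ranges
    displacements: Optional[dict] = None
    post_displacements: Optional[dict] = None
    make_post: bool = False
    normal_range: tuple = (2.0, 8.0)
    tangential_range: tuple = (2.0, 20.0)
    rotation_deg_max: float = 0.0
    post_normal_range: tuple = (0.5, 2.0)
    post_tangential_range: tuple = (1.0, 5.0)
    with_fins: bool = True
    edge_length: float = DEFAULT.phantom_edge
    cup_center: tuple = (40.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if not (self.cup_radius > self.shell_thickness > 0):
            raise ValueError("need cup_radius > shell_thickness > 0")
        az = np.asarray(self.sector_azimuths_deg, dtype=float)
        if az.size < 2 or np.any(np.diff(az) <= 0) or az[-1] - az[0] >= 360:
            raise ValueError("sector azimuths must be strictly increasing within one turn")

    @property
    def n_fragments(self) -> int:
        return len(self.sector_azimuths_deg)

    @property
    def outer_radius(self) -> float:
        return self.cup_radius + self.shell_thickness


@dataclass
class LineTruth:
    """Exact displacement summary along one fracture line."""

    fragment_id: str
    adjacent_fragment_id: Optional[str]
    max_step_off: float
    mean_step_off: float
    max_gap: float
    mean_gap: float
    length: float


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom."""

    applied: dict                      # fragment_id -> RigidTransform (reduced->displaced)
    lines: list                        # list[LineTruth], pre state
    max_step_off: float
    mean_step_off: float
    max_gap: float
    mean_gap: float
    applied_post: Optional[dict] = None
    lines_post: Optional[list] = None
    post_max_step_off: Optional[float] = None
    post_mean_step_off: Optional[float] = None
    post_max_gap: Optional[float] = None
    post_mean_gap: Optional[float] = None
    total_gap_area: Optional[float] = None   # analytic only where tractable
    cup_center: Optional[np.ndarray] = None
    cup_axis: Optional[np.ndarray] = None
    cup_radius: Optional[float] = None


@dataclass
class Phantom:
    """Everything :func:`make_phantom` produces."""

    pre: FragmentSet
    intact: trimesh.Trimesh            # contralateral (mirror-image) intact side
    landmarks: LandmarkSet
    truth: PhantomTruth
    spec: PhantomSpec
    post: Optional[FragmentSet] = None
    post_model: Optional[trimesh.Trimesh] = None
    template: Optional[trimesh.Trimesh] = None  # intact geometry on the fractured side
    symmetry_plane: Plane = field(
        default_factory=lambda: Plane(point=np.zeros(3), normal=np.array([1.0, 0.0, 0.0]))
    )


# ---------------------------------------------------------------------------
# canonical-frame shell construction (cup opens toward +z, apex at -z, rim z=0)


def _quads(a, b, c, d):
    """Triangulate quads given four equal-length index arrays (a,b,c,d CCW)."""
    return np.concatenate(
        [np.stack([a, b, c], axis=-1), np.stack([a, c, d], axis=-1)], axis=0
    )


def _shell(Ri: float, Ro: float, phi0: float, phi1: float, edge: float,
           full: bool = False) -> trimesh.Trimesh:
    """Watertight shell wedge for azimuth sector [phi0, phi1] (radians).

    Winding is constructed outward-consistent analytically (outer surface
    radially out, inner surface toward the cup centre, rim strip +z, cut
    faces out of the sector), so no orientation repair pass is needed.
    """
    ntheta = max(4, int(np.ceil((np.pi / 2) * Ro / edge)))
    if full:
        nphi = max(8, int(np.ceil(2 * np.pi * Ro / edge)))
        J = nphi
        phis = np.linspace(0.0, 2 * np.pi, nphi, endpoint=False)
    else:
        nphi = max(3, int(np.ceil((phi1 - phi0) * Ro / edge)))
        J = nphi + 1
        phis = np.linspace(phi0, phi1, J)
    thetas = np.linspace(0.0, np.pi / 2, ntheta + 1)[1:]  # apex handled separately

    def surf(r):
        th, ph = np.meshgrid(thetas, phis, indexing="ij")
        return np.stack(
            [r * np.sin(th) * np.cos(ph), r * np.sin(th) * np.sin(ph), -r * np.cos(th)],
            axis=-1,
        ).reshape(-1, 3)

    # vertex layout: [apex_in, inner grid, apex_out, outer grid]
    o_in, o_out = 1, 1 + ntheta * J + 1
    verts = np.vstack(
        [np.array([[0.0, 0.0, -Ri]]), surf(Ri), np.array([[0.0, 0.0, -Ro]]), surf(Ro)]
    )

    jmax = J if full else J - 1
    j = np.arange(jmax)
    jp = (j + 1) % J

    def grid(offset, i, jj):
        return offset + i * J + jj

    faces = []
    ii = np.arange(ntheta - 1)[:, None]
    for offset, apex, flip in ((o_in, 0, False), (o_out, o_out - 1, True)):
        # apex fan: inner (apex, j, j+1); outer reversed
        fan = np.stack(
            [np.full(jmax, apex), grid(offset, 0, jp), grid(offset, 0, j)], axis=-1
        )
        # ring quads, CCW from outside: outer is (i,j),(i,j+1),(i+1,j+1),(i+1,j)
        q = _quads(
            grid(offset, ii, j).ravel(), grid(offset, ii, jp).ravel(),
            grid(offset, ii + 1, jp).ravel(), grid(offset, ii + 1, j).ravel(),
        )
        if not flip:  # inner surface: reverse winding
            fan = fan[:, ::-1]
            q = q[:, ::-1]
        faces.extend([fan, q])
    # rim strip between inner and outer boundary rings (theta = pi/2), normal +z
    faces.append(
        _quads(
            grid(o_in, ntheta - 1, j), grid(o_out, ntheta - 1, j),
            grid(o_out, ntheta - 1, jp), grid(o_in, ntheta - 1, jp),
        )
    )
    if not full:
        # planar cut faces at phi0 (j=0, outward -phi_hat) and phi1 (outward +phi_hat)
        i = np.arange(ntheta)
        for jcol, reverse in ((0, True), (J - 1, False)):
            col_in = np.concatenate([[0], grid(o_in, np.arange(ntheta), jcol)])
            col_out = np.concatenate([[o_out - 1], grid(o_out, np.arange(ntheta), jcol)])
            q = _quads(col_in[:-1], col_in[1:], col_out[1:], col_out[:-1])
            if reverse:
                q = q[:, ::-1]
            faces.append(q)

    mesh = trimesh.Trimesh(vertices=verts, faces=np.vstack(faces), process=False)
    if mesh.volume < 0:  # safety net; construction should already be outward
        mesh.invert()
    return mesh


def _fin(phi: float, Ro: float, k: int = 0) -> trimesh.Trimesh:
    """Extra-articular wing at azimuth ``phi``: a radial slab rooted in the shell.

    Emulates the peri-acetabular bone a real fragment carries (iliac wing,
    pubic ramus, ischium): it reaches well beyond any plausible fragment
    displacement, so surface registration stays anchored even at 20 mm of
    initial displacement.  Per-fragment dimensions differ (``k``) so that no
    two fragments are congruent.
    """
    length, width, thick = 26.0 + 4.0 * k, 6.0 + 2.0 * k, 8.0
    box = trimesh.creation.box(extents=(length, width, thick))
    r_hat = np.array([np.cos(phi), np.sin(phi), 0.0])
    t_hat = np.array([-np.sin(phi), np.cos(phi), 0.0])
    z_hat = np.array([0.0, 0.0, 1.0])
    T = np.eye(4)
    T[:3, :3] = np.column_stack([r_hat, t_hat, z_hat])
    T[:3, 3] = (Ro - 3.0 + length / 2.0) * r_hat + np.array([0.0, 0.0, -6.0])
    box.apply_transform(T)
    return box


#: canonical->world rotation: the cup opens laterally (+x on the right side)
_FRAME = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])


def _to_world(mesh: trimesh.Trimesh, center: np.ndarray) -> trimesh.Trimesh:
    T = np.eye(4)
    T[:3, :3] = _FRAME
    T[:3, 3] = center
    out = mesh.copy()
    out.apply_transform(T)
    return out


def _mirror_x0(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    out = mesh.copy()
    v = out.vertices.copy()
    v[:, 0] *= -1.0
    out.vertices = v
    out.invert()  # reflection flips orientation; restore outward normals
    return out


# ---------------------------------------------------------------------------
# displacements


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def draw_displacements(
    spec: PhantomSpec,
    seed: int,
    normal_range: tuple,
    tangential_range: tuple,
    rotation_deg_max: float,
) -> dict:
    """Random per-fragment rigid displacements with controlled step/gap content.

    The translation of each fragment is composed of a component along the
    articular normal at the fragment's reference point (drawn from
    ``normal_range``, random sign) and a component in a random tangential
    direction (``tangential_range``); an optional small rotation about the
    reference point is added on top.
    """
    rng = _rng(seed)
    c = np.asarray(spec.cup_center, dtype=float)
    az = np.radians(np.asarray(spec.sector_azimuths_deg, dtype=float))
    bounds = np.append(az, az[0] + 2 * np.pi)
    out = {}
    for k in range(spec.n_fragments):
        phi_mid = 0.5 * (bounds[k] + bounds[k + 1])
        theta_ref = np.pi / 4
        p_can = spec.cup_radius * np.array(
            [np.sin(theta_ref) * np.cos(phi_mid), np.sin(theta_ref) * np.sin(phi_mid),
             -np.cos(theta_ref)]
        )
        p_ref = _FRAME @ p_can + c
        n = (c - p_ref) / np.linalg.norm(c - p_ref)
        # random tangential unit vector
        t = rng.normal(size=3)
        t -= np.dot(t, n) * n
        t /= np.linalg.norm(t)
        s = rng.uniform(*normal_range) * rng.choice([-1.0, 1.0])
        g = rng.uniform(*tangential_range)
        u = s * n + g * t
        if rotation_deg_max > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = np.radians(rng.uniform(0, rotation_deg_max))
            K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        else:
            R = np.eye(3)
        # rotate about p_ref, then translate by u
        out[f"frag{k}"] = RigidTransform(rotation=R, translation=p_ref - R @ p_ref + u)
    return out


# ---------------------------------------------------------------------------
# ground truth


def _boundary_lines(spec: PhantomSpec):
    """Fracture lines in reduced (intact) pose, grouped per unordered fragment pair.

    Each sector boundary contributes the half great circle arc (apex to rim)
    where the cut plane meets the articular sphere.  In the two-fragment case
    both boundaries join the same pair, forming one line through the apex.
    """
    c = np.asarray(spec.cup_center, dtype=float)
    az = np.radians(np.asarray(spec.sector_azimuths_deg, dtype=float))
    nb = len(az)
    per_pair: dict = {}
    for b in range(nb):
        phi = az[b]
        left = (b - 1) % nb   # sector ending at this boundary
        right = b             # sector starting at this boundary
        pair = (min(left, right), max(left, right))
        n_pts = max(2, int(np.ceil((np.pi / 2) * spec.cup_radius / TRUTH_STEP)) + 1)
        thetas = np.linspace(0.0, np.pi / 2, n_pts)
        pts_can = spec.cup_radius * np.stack(
            [np.sin(thetas) * np.cos(phi), np.sin(thetas) * np.sin(phi),
             -np.cos(thetas)], axis=-1
        )
        pts = pts_can @ _FRAME.T + c
        per_pair.setdefault(pair, []).append(pts)
    return per_pair


def _truth_lines(spec: PhantomSpec, transforms: dict):
    """Analytic per-line displacement truth for the given applied transforms."""
    c = np.asarray(spec.cup_center, dtype=float)
    lines = []
    all_step, all_gap = [], []
    for (i, j), chunks in sorted(_boundary_lines(spec).items()):
        Ti, Tj = transforms[f"frag{i}"], transforms[f"frag{j}"]
        length = sum(
            float(np.linalg.norm(np.diff(ch, axis=0), axis=1).sum()) for ch in chunks
        )
        pts = np.vstack(chunks)
        d = Ti.apply(pts) - Tj.apply(pts)
        n = (c - pts) / np.linalg.norm(c - pts, axis=1, keepdims=True)
        step, gap = decompose_displacement(d, n)
        lines.append(
            LineTruth(
                fragment_id=f"frag{i}",
                adjacent_fragment_id=f"frag{j}",
                max_step_off=float(step.max()),
                mean_step_off=float(step.mean()),
                max_gap=float(gap.max()),
                mean_gap=float(gap.mean()),
                length=length,
            )
        )
        all_step.append(step)
        all_gap.append(gap)
    step = np.concatenate(all_step)
    gap = np.concatenate(all_gap)
    return lines, float(step.max()), float(step.mean()), float(gap.max()), float(gap.mean())


# ---------------------------------------------------------------------------
# main constructors


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> Phantom:
    """Build the fractured cup, intact contralateral side, landmarks and truth."""
    Ri, Ro = spec.cup_radius, spec.outer_radius
    c = np.asarray(spec.cup_center, dtype=float)
    az = np.radians(np.asarray(spec.sector_azimuths_deg, dtype=float))
    bounds = np.append(az, az[0] + 2 * np.pi)

    # reduced-pose fragments (canonical frame -> world)
    frag_meshes, frag_ids = [], []
    for k in range(spec.n_fragments):
        wedge = _shell(Ri, Ro, bounds[k], bounds[k + 1], spec.edge_length)
        parts = [wedge]
        if spec.with_fins:
            parts.append(_fin(0.5 * (bounds[k] + bounds[k + 1]), Ro, k))
        mesh = _to_world(trimesh.util.concatenate(parts), c)
        mesh.metadata["fragment_id"] = f"frag{k}"
        frag_meshes.append(mesh)
        frag_ids.append(f"frag{k}")

    # intact geometry: full shell + all fins; template on fractured side,
    # mirrored across the midsagittal plane for the contralateral side
    intact_parts = [_shell(Ri, Ro, 0.0, 2 * np.pi, spec.edge_length, full=True)]
    if spec.with_fins:
        for k in range(spec.n_fragments):
            intact_parts.append(_fin(0.5 * (bounds[k] + bounds[k + 1]), Ro, k))
    template = _to_world(trimesh.util.concatenate(intact_parts), c)
    template.metadata["fragment_id"] = "intact_template"
    intact = _mirror_x0(template)
    intact.metadata["fragment_id"] = "intact_contralateral"

    # landmarks on the rim plane (world), >5 mm apart, on the known cup-axis plane
    lm_phis = np.radians([40.0, 160.0, 280.0])
    lm_pts = {
        name: _FRAME @ ((Ro + 3.0) * np.array([np.cos(p), np.sin(p), 0.0])) + c
        for name, p in zip(REQUIRED_LANDMARKS, lm_phis)
    }
    landmarks = LandmarkSet(points=lm_pts)

    # applied displacements
    applied = spec.displacements or draw_displacements(
        spec, spec.seed, spec.normal_range, spec.tangential_range, spec.rotation_deg_max
    )
    pre_meshes = []
    for fid, m in zip(frag_ids, frag_meshes):
        dm = m.copy()
        dm.apply_transform(applied[fid].to_matrix())
        dm.metadata["fragment_id"] = fid
        pre_meshes.append(dm)
    pre = FragmentSet(meshes=pre_meshes, fragment_ids=list(frag_ids), source="pre")

    lines, mx_s, mn_s, mx_g, mn_g = _truth_lines(spec, applied)
    truth = PhantomTruth(
        applied=applied, lines=lines,
        max_step_off=mx_s, mean_step_off=mn_s, max_gap=mx_g, mean_gap=mn_g,
        cup_center=c, cup_axis=_FRAME @ np.array([0.0, 0.0, 1.0]), cup_radius=Ri,
    )

    post = post_model = None
    if spec.make_post or spec.post_displacements is not None:
        applied_post = spec.post_displacements or draw_displacements(
            spec, spec.seed + 10_000, spec.post_normal_range,
            spec.post_tangential_range, 0.0,
        )
        post_meshes = []
        for fid, m in zip(frag_ids, frag_meshes):
            dm = m.copy()
            dm.apply_transform(applied_post[fid].to_matrix())
            dm.metadata["fragment_id"] = fid
            post_meshes.append(dm)
        post = FragmentSet(meshes=post_meshes, fragment_ids=list(frag_ids), source="post")
        post_model = trimesh.util.concatenate(post_meshes)
        post_model.metadata["fragment_id"] = "post_model"
        pl, pmx_s, pmn_s, pmx_g, pmn_g = _truth_lines(spec, applied_post)
        truth.applied_post = applied_post
        truth.lines_post = pl
        truth.post_max_step_off, truth.post_mean_step_off = pmx_s, pmn_s
        truth.post_max_gap, truth.post_mean_gap = pmx_g, pmn_g

    return Phantom(
        pre=pre, intact=intact, landmarks=landmarks, truth=truth, spec=spec,
        post=post, post_model=post_model, template=template,
    )


def make_flat_patch_phantom(
    length: float = 20.0,
    half_width: float = 10.0,
    thickness: float = 4.0,
    displacements: Optional[dict] = None,
) -> Phantom:
    """Two slabs sharing a straight edge: a planar articular facet.

    On a curved cup a purely tangential translation induces a small nonzero
    step-off (the normal tilts along the line), so exact decomposition tests
    use this planar patch where normal and tangential are globally constant:
    the articular surface is the plane z = 0 with outward normal +z and the
    fracture line runs along x from (0,0,0) to (length,0,0).
    """
    def slab(y0, y1):
        box = trimesh.creation.box(extents=(length, y1 - y0, thickness))
        box.apply_translation([length / 2, (y0 + y1) / 2, -thickness / 2])
        return box

    frag_ids = ["frag0", "frag1"]
    meshes = [slab(0.0, half_width), slab(-half_width, 0.0)]
    for fid, m in zip(frag_ids, meshes):
        m.metadata["fragment_id"] = fid
    template = slab(-half_width, half_width)
    template.metadata["fragment_id"] = "intact_template"
    intact = _mirror_x0(template)

    applied = displacements or {fid: RigidTransform.identity() for fid in frag_ids}
    pre_meshes = []
    for fid, m in zip(frag_ids, meshes):
        dm = m.copy()
        dm.apply_transform(applied[fid].to_matrix())
        dm.metadata["fragment_id"] = fid
        pre_meshes.append(dm)
    pre = FragmentSet(meshes=pre_meshes, fragment_ids=frag_ids, source="pre")

    n_pts = max(2, int(np.ceil(length / TRUTH_STEP)) + 1)
    pts = np.column_stack(
        [np.linspace(0, length, n_pts), np.zeros(n_pts), np.zeros(n_pts)]
    )
    d = applied["frag0"].apply(pts) - applied["frag1"].apply(pts)
    n = np.tile([0.0, 0.0, 1.0], (n_pts, 1))
    step, gap = decompose_displacement(d, n)
    # analytic ribbon area (translations only): parallelogram between the two
    # displaced copies of the line, viewed along +z
    r = applied["frag0"].translation - applied["frag1"].translation
    rot_free = np.allclose(applied["frag0"].rotation, np.eye(3)) and np.allclose(
        applied["frag1"].rotation, np.eye(3)
    )
    area = float(length * abs(r[1])) if rot_free else None
    truth = PhantomTruth(
        applied=applied,
        lines=[
            LineTruth(
                fragment_id="frag0", adjacent_fragment_id="frag1",
                max_step_off=float(step.max()), mean_step_off=float(step.mean()),
                max_gap=float(gap.max()), mean_gap=float(gap.mean()),
                length=float(length),
            )
        ],
        max_step_off=float(step.max()), mean_step_off=float(step.mean()),
        max_gap=float(gap.max()), mean_gap=float(gap.mean()),
        total_gap_area=area,
        cup_center=None, cup_axis=np.array([0.0, 0.0, 1.0]), cup_radius=None,
    )
    lm = LandmarkSet(
        points={
            REQUIRED_LANDMARKS[0]: (0.0, -half_width, 0.0),
            REQUIRED_LANDMARKS[1]: (length, -half_width, 0.0),
            REQUIRED_LANDMARKS[2]: (length / 2, half_width, 0.0),
        }
    )
    return Phantom(
        pre=pre, intact=intact, landmarks=lm, truth=truth,
        spec=PhantomSpec(), template=template,
    )


# ---------------------------------------------------------------------------
# voxelization (pseudo-CT)


def _slice_mask(segments_2d: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Even-odd scanline fill of a closed cross-section given as a segment soup."""
    mask = np.zeros((len(xs), len(ys)), dtype=bool)
    if len(segments_2d) == 0:
        return mask
    p, q = segments_2d[:, 0, :], segments_2d[:, 1, :]
    for j, y in enumerate(ys):
        crosses = (p[:, 1] > y) != (q[:, 1] > y)
        if not crosses.any():
            continue
        pc, qc = p[crosses], q[crosses]
        t = (y - pc[:, 1]) / (qc[:, 1] - pc[:, 1])
        xc = np.sort(pc[:, 0] + t * (qc[:, 0] - pc[:, 0]))
        mask[:, j] = (np.searchsorted(xc, xs) % 2) == 1
    return mask


def voxelize(
    meshes,
    spacing=1.0,
    bone_hu: float = 700.0,
    background_hu: float = 0.0,
    margin_voxels: int = 2,
) -> VoxelVolume:
    """Rasterize watertight meshes into a pseudo-CT volume.

    Voxels whose centre lies inside any mesh get ``bone_hu``, all others
    ``background_hu``.  Non-watertight concatenations are split into their
    watertight components first.  Interiors are resolved per z-slice by
    even-odd scanline filling of the mesh cross-section, which is exact for
    closed surfaces and needs no ray-casting acceleration.
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    components = []
    for m in meshes:
        if m.is_watertight:
            components.append(m)
        else:
            components.extend(m.split(only_watertight=True))
    if components:
        lo = np.min([m.bounds[0] for m in components], axis=0) - margin_voxels * spacing
        hi = np.max([m.bounds[1] for m in components], axis=0) + margin_voxels * spacing
    else:
        lo, hi = np.zeros(3), spacing * 8
    shape = np.maximum(2, np.ceil((hi - lo) / spacing).astype(int))
    affine = np.diag(np.append(spacing, 1.0))
    affine[:3, 3] = lo + spacing / 2.0  # voxel centres

    xs = lo[0] + spacing[0] * (np.arange(shape[0]) + 0.5)
    ys = lo[1] + spacing[1] * (np.arange(shape[1]) + 0.5)
    zs = lo[2] + spacing[2] * (np.arange(shape[2]) + 0.5)
    occ = np.zeros(tuple(shape), dtype=bool)
    eps = 1e-6  # nudge slice planes off exact vertex coordinates
    for m in components:
        zlo, zhi = m.bounds[0][2], m.bounds[1][2]
        for k, z in enumerate(zs):
            if z < zlo or z > zhi:
                continue
            seg = trimesh.intersections.mesh_plane(
                m, plane_normal=[0.0, 0.0, 1.0], plane_origin=[0.0, 0.0, z + eps]
            )
            if len(seg) == 0:
                continue
            occ[:, :, k] |= _slice_mask(np.asarray(seg)[:, :, :2], xs, ys)
    data = np.where(occ, bone_hu, background_hu)
    return VoxelVolume(data=data, affine=affine)


# ---------------------------------------------------------------------------
# synthetic rater tables


def make_rater_table(
    true_values,
    rater_bias=0.0,
    rater_noise_sd: float = 0.0,
    seed: int = 0,
    n_raters: int = 2,
) -> np.ndarray:
    """Emulate independent observers measuring the same subjects.

    Column ``j`` is ``true + bias_j + N(0, sd)``; the expected agreement ICC
    follows from the variance components, sigma_s^2 / (sigma_s^2 + sigma_b^2
    + sigma_e^2).
    """
    if rater_noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    true_values = np.asarray(true_values, dtype=float)
    bias = np.broadcast_to(np.asarray(rater_bias, dtype=float), (n_raters,))
    rng = _rng(seed)
    noise = rng.normal(0.0, rater_noise_sd, size=(len(true_values), n_raters))
    return true_values[:, None] + bias[None, :] + noise
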