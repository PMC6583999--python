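"""Mirror template and ICP virtual reduction."""

import numpy as np
import pytest
import trimesh
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from fract3d.geometry import Plane, RigidTransform
from fract3d.io import FragmentSet
from fract3d.reduction import (build_mirror_template, icp_register,
                               match_pre_to_post, reduce_fragments,
                               symmetry_plane_from_landmarks)


def _asym_target():
    """Asymmetric polyhedral target: flat faces make point-to-plane exact."""
    a = trimesh.creation.box(extents=(40, 22, 10))
    b = trimesh.creation.box(extents=(12, 12, 34))
    b.apply_translation([10, 3, 12])
    c = trimesh.creation.box(extents=(26, 8, 8))
    c.apply_translation([-12, -9, 7])
    return trimesh.util.concatenate([a, b, c])


def test_mirror_template_negates_x(cup_phantom):
    plane = Plane(point=(0, 0, 0), normal=(1, 0, 0))
    tmpl = build_mirror_template(cup_phantom.intact, plane)
    v = cup_phantom.intact.vertices.copy()
    v[:, 0] *= -1
    assert np.abs(tmpl.vertices - v).max() < 1e-12


def test_double_mirror_recovers_original(cup_phantom):
    plane = Plane(point=(3.0, -2.0, 1.0), normal=(1.0, 2.0, -1.0))
    once = build_mirror_template(cup_phantom.intact, plane)
    twice = build_mirror_template(once, plane)
    assert np.abs(twice.vertices - cup_phantom.intact.vertices).max() < 1e-9


def test_mirrored_cup_registers_onto_contralateral(cup_phantom, template):
    """Bilateral symmetry: mirrored intact fits the fractured side's anatomy."""
    src, _ = trimesh.sample.sample_surface(template, 2000, seed=0)
    reg = icp_register(np.asarray(src), cup_phantom.template, seed=0)
    assert reg.rms < 0.1
    assert np.linalg.norm(reg.transform.translation) < 0.05


def test_symmetry_plane_from_landmarks():
    left = [(-40, 0, 0), (-30, 10, 5)]
    right = [(40, 0, 0), (30, 10, 5)]
    plane = symmetry_plane_from_landmarks(left, right)
    assert abs(abs(plane.normal[0]) - 1.0) < 1e-12
    assert abs(plane.point[0]) < 1e-12


def test_icp_identity_on_self():
    target = _asym_target()
    src, _ = trimesh.sample.sample_surface(target, 1500, seed=1)
    reg = icp_register(np.asarray(src), target, seed=1)
    assert reg.rms < 0.5
    assert np.linalg.norm(reg.transform.translation) < 1e-2
    assert reg.transform.rotation_angle_deg() < 1e-2


def test_icp_recovers_known_transform():
    """10 deg about z + (5,0,0) translation is inverted to ~1e-3 accuracy."""
    target = _asym_target()
    src, _ = trimesh.sample.sample_surface(target, 3000, seed=2)
    R = Rotation.from_euler("z", 10, degrees=True).as_matrix()
    T_applied = RigidTransform(rotation=R, translation=(5.0, 0.0, 0.0))
    moved = T_applied.apply(np.asarray(src))
    reg = icp_register(moved, target, seed=2)
    resid = reg.transform.compose(T_applied)
    assert np.linalg.norm(resid.translation) < 1e-3
    assert resid.rotation_angle_deg() < 1e-3


def test_icp_rejects_too_few_or_collinear_points():
    target = _asym_target()
    with pytest.raises(ValueError):
        icp_register(np.array([[0.0, 0, 0], [1, 0, 0]]), target)
    line = np.column_stack([np.linspace(0, 10, 30), np.zeros(30), np.zeros(30)])
    with pytest.raises(ValueError):
        icp_register(line, target)


def test_icp_equivariant_under_common_rotation():
    """Rotating source and target together conjugates the recovered transform."""
    target = _asym_target()
    src, _ = trimesh.sample.sample_surface(target, 2000, seed=3)
    T_applied = RigidTransform(
        rotation=Rotation.from_euler("y", 6, degrees=True).as_matrix(),
        translation=(3.0, -2.0, 1.0),
    )
    moved = T_applied.apply(np.asarray(src))
    reg0 = icp_register(moved, target, seed=3)

    Q = Rotation.from_euler("xz", [12, -20], degrees=True).as_matrix()
    TQ = RigidTransform(rotation=Q, translation=(0.0, 0.0, 0.0))
    target_q = target.copy()
    target_q.vertices = TQ.apply(target_q.vertices)
    reg1 = icp_register(TQ.apply(moved), target_q, seed=3)
    conj = TQ.compose(reg0.transform).compose(TQ.inverse())
    resid = reg1.transform.compose(conj.inverse())
    assert np.linalg.norm(resid.translation) < 1e-3
    assert resid.rotation_angle_deg() < 1e-3


def test_reduce_fragments_recovers_applied_displacements(cup_phantom, template,
                                                         reduction):
    """The virtual reduction inverts the known displacements to < 0.1 mm."""
    for fid in cup_phantom.pre.fragment_ids:
        resid = reduction.transforms[fid].compose(cup_phantom.truth.applied[fid])
        assert np.linalg.norm(resid.translation) < 0.1
        assert resid.rotation_angle_deg() < 0.1
    assert reduction.unreduced == []


def test_reduce_already_reduced_is_near_identity(cup_phantom, template):
    ids = list(cup_phantom.pre.fragment_ids)
    meshes = []
    for fid, m in cup_phantom.pre:
        rm = m.copy()
        rm.apply_transform(cup_phantom.truth.applied[fid].inverse().to_matrix())
        meshes.append(rm)
    frags = FragmentSet(meshes=meshes, fragment_ids=ids)
    red = reduce_fragments(frags, template)
    for fid in ids:
        assert np.linalg.norm(red.transforms[fid].translation) < 0.05


def test_foreign_fragment_flagged_unreduced(template):
    """Geometry from a different bone cannot be explained by the template."""
    alien = trimesh.creation.box(extents=(70, 55, 40))
    alien.apply_translation(template.vertices.mean(axis=0))
    frags = FragmentSet(meshes=[alien], fragment_ids=["alien"])
    red = reduce_fragments(frags, template)
    assert red.unreduced == ["alien"]


def test_match_pre_to_post_recovers_residual():
    """Post model built from known residual transforms is matched < 0.1 mm."""
    from fract3d.phantom import PhantomSpec, make_phantom
    from fract3d.geometry import Plane

    ph = make_phantom(PhantomSpec(seed=7, make_post=True))
    template = build_mirror_template(ph.intact, Plane(point=(0, 0, 0), normal=(1, 0, 0)))
    red = reduce_fragments(ph.pre, template)
    match = match_pre_to_post(ph.pre, ph.post_model, red)
    for fid in ph.pre.fragment_ids:
        # displaced(pre) -> post should equal T_post o T_pre^-1
        expected = ph.truth.applied_post[fid].compose(ph.truth.applied[fid].inverse())
        resid = match.transforms[fid].compose(expected.inverse())
        assert np.linalg.norm(resid.translation) < 0.1
        assert resid.rotation_angle_deg() < 0.1
    assert match.unreduced == []


def test_registration_rms_nonnegative(reduction):
    assert all(v >= 0 for v in reduction.rms.values())
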