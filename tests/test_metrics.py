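"""Fracture-line extraction, displacement profiles and the 2D emulator."""

import numpy as np
import pytest

from fract3d.config import DEFAULT
from fract3d.geometry import Plane, RigidTransform
from fract3d.io import FragmentSet
from fract3d.metrics import (FractureLine, PlanarPatchRegion, SphericalCupRegion,
                             dedupe_interior, displacement_profile,
                             extract_fracture_lines, resample_polyline,
                             slice_2d_measurement, summarize)
from fract3d.phantom import PhantomSpec, make_flat_patch_phantom, make_phantom


def _reduced_set(ph):
    """Fragments moved back to reduced pose using the exact truth transforms."""
    meshes = []
    for fid, m in ph.pre:
        rm = m.copy()
        rm.apply_transform(ph.truth.applied[fid].inverse().to_matrix())
        rm.metadata["fragment_id"] = fid
        meshes.append(rm)
    return FragmentSet(meshes=meshes, fragment_ids=list(ph.pre.fragment_ids))


def _profiles(ph, lines, region, poses=None):
    poses = poses or ph.truth.applied
    return [
        displacement_profile(
            ln, poses[ln.fragment_id],
            poses[ln.adjacent_fragment_id] if ln.adjacent_fragment_id else None,
            region,
        )
        for ln in lines
    ]


# ---------------------------------------------------------------------------
# region fitting and extraction


def test_sphere_fit_recovers_articular_surface(region, cup_phantom):
    assert region.radius == pytest.approx(cup_phantom.spec.cup_radius, abs=0.05)
    assert np.allclose(region.center, cup_phantom.truth.cup_center, atol=0.05)


def test_extracted_line_is_half_great_circle(cup_phantom, region):
    """One apex cut: each fragment carries one line of length ~ pi * R."""
    lines = extract_fracture_lines(_reduced_set(cup_phantom), region,
                                   cup_phantom.template)
    by_frag = {ln.fragment_id: ln for ln in lines}
    assert set(by_frag) == {"frag0", "frag1"}
    expected = np.pi * cup_phantom.spec.cup_radius
    for ln in by_frag.values():
        assert ln.length == pytest.approx(expected, abs=2.0)
        assert ln.spacing <= DEFAULT.resample_step + 1e-9
        # points lie on the articular sphere
        r = np.linalg.norm(ln.points - region.center, axis=1)
        assert np.abs(r - region.radius).max() < 0.3


def test_unfractured_cup_yields_no_lines(cup_phantom, region):
    whole = FragmentSet(meshes=[cup_phantom.template.copy()], fragment_ids=["whole"])
    assert extract_fracture_lines(whole, region, cup_phantom.template) == []


def test_three_fragment_reciprocal_adjacency():
    ph = make_phantom(PhantomSpec(seed=5, sector_azimuths_deg=(0.0, 120.0, 240.0)))
    region = SphericalCupRegion.fit(ph.template)
    lines = extract_fracture_lines(_reduced_set(ph), region, ph.template)
    pairs = {(ln.fragment_id, ln.adjacent_fragment_id) for ln in lines}
    for a, b in pairs:
        assert (b, a) in pairs, f"line {a}->{b} lacks its reciprocal"


def test_resampling_halving_is_stable(cup_phantom, region):
    """Halving the resample step changes max summaries by < 0.05 mm."""
    reduced = _reduced_set(cup_phantom)
    summaries = []
    for step in (DEFAULT.resample_step, DEFAULT.resample_step / 2):
        cfg = DEFAULT.with_(resample_step=step)
        lines = extract_fracture_lines(reduced, region, cup_phantom.template, cfg)
        profs = dedupe_interior(_profiles(cup_phantom, lines, region))
        summaries.append(summarize(profs))
    assert abs(summaries[0].max_gap - summaries[1].max_gap) < 0.05
    assert abs(summaries[0].max_step_off - summaries[1].max_step_off) < 0.05


def test_resample_polyline_spacing():
    pts = np.array([[0.0, 0, 0], [10.0, 0, 0]])
    out = resample_polyline(pts, 0.5)
    assert len(out) == 21
    assert np.allclose(np.diff(out[:, 0]), 0.5)


# ---------------------------------------------------------------------------
# profiles on the flat patch (exact decomposition, no curvature leakage)


def _flat_line_and_region(length=20.0):
    line = FractureLine(
        points=resample_polyline(np.array([[0.0, 0, 0], [length, 0, 0]]), 0.5),
        fragment_id="frag0", adjacent_fragment_id="frag1",
    )
    region = PlanarPatchRegion(plane=Plane(point=(0, 0, 0), normal=(0, 0, 1)))
    return line, region


def test_profile_zero_for_identity_poses():
    line, region = _flat_line_and_region()
    prof = displacement_profile(line, RigidTransform.identity(),
                                RigidTransform.identity(), region)
    assert np.all(prof.step_off == 0)
    assert np.all(prof.gap == 0)


def test_profile_pure_normal_translation():
    """Own fragment 3 mm along the facet normal: step 3, gap 0 everywhere."""
    line, region = _flat_line_and_region()
    prof = displacement_profile(
        line, RigidTransform(translation=(0, 0, 3.0)),
        RigidTransform.identity(), region,
    )
    assert np.allclose(prof.step_off, 3.0, atol=1e-12)
    assert np.allclose(prof.gap, 0.0, atol=1e-12)
    assert np.allclose(prof.signed_step_off, 3.0)


def test_profile_pure_tangential_translation_on_cup():
    """4 mm tangentially on an R=25 cup: gap ~ 4, curvature leakage < 0.15."""
    R = 25.0
    region = SphericalCupRegion(center=np.zeros(3), radius=R)
    theta = np.linspace(np.pi / 3, 2 * np.pi / 3, 80)
    pts = R * np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
    line = FractureLine(points=pts, fragment_id="frag0", adjacent_fragment_id="frag1")
    prof = displacement_profile(
        line, RigidTransform(translation=(0, 0, 4.0)),  # tangent to the sphere belt
        RigidTransform.identity(), region,
    )
    assert np.allclose(prof.gap, 4.0, atol=0.01)
    assert prof.step_off.max() < 0.15


def test_profile_requires_adjacent_pose():
    line, region = _flat_line_and_region()
    with pytest.raises(ValueError):
        displacement_profile(line, RigidTransform.identity(), None, region)


def test_peripheral_line_measures_against_reduced_pose():
    line, region = _flat_line_and_region()
    peripheral = FractureLine(points=line.points, fragment_id="frag0",
                              adjacent_fragment_id=None)
    prof = displacement_profile(
        peripheral, RigidTransform(translation=(0, 0, 2.0)), None, region)
    assert np.allclose(prof.step_off, 2.0)


# ---------------------------------------------------------------------------
# summaries


def test_summarize_single_profile():
    line, region = _flat_line_and_region(1.0)
    line = FractureLine(points=np.array([[0.0, 0, 0], [0.5, 0, 0], [1.0, 0, 0]]),
                        fragment_id="a", adjacent_fragment_id="b")
    prof = displacement_profile(line, RigidTransform(translation=(0, 0, 2.0)),
                                RigidTransform.identity(), region)
    prof.step_off = np.array([1.0, 2.0, 3.0])
    prof.gap = np.array([0.0, 0.0, 0.0])
    s = summarize([prof])
    assert s.max_step_off == 3.0
    assert s.mean_step_off == pytest.approx(2.0)


def test_summarize_arc_length_weighted_mean():
    """Two lines of different spacing: mean equals brute-force enumeration."""
    _, region = _flat_line_and_region()

    def make(npts, length, value):
        pts = np.column_stack([np.linspace(0, length, npts),
                               np.zeros(npts), np.zeros(npts)])
        line = FractureLine(points=pts, fragment_id="a", adjacent_fragment_id="b")
        prof = displacement_profile(line, RigidTransform(translation=(0, 0, value)),
                                    RigidTransform.identity(), region)
        return prof

    p1 = make(11, 5.0, 1.0)   # spacing 0.5, step-off 1
    p2 = make(41, 10.0, 4.0)  # spacing 0.25, step-off 4
    s = summarize([p1, p2])
    # brute-force: each point weighted by its line's spacing
    values = np.concatenate([np.full(11, 1.0), np.full(41, 4.0)])
    weights = np.concatenate([np.full(11, 0.5), np.full(41, 0.25)])
    assert s.mean_step_off == pytest.approx(values @ weights / weights.sum())
    assert s.max_step_off == 4.0


def test_summarize_empty_rejected():
    with pytest.raises(ValueError):
        summarize([])


def test_analytic_correspondence_matches_truth(cup_phantom, region):
    """With exact poses the measured summaries equal ground truth < 0.05 mm."""
    lines = extract_fracture_lines(_reduced_set(cup_phantom), region,
                                   cup_phantom.template)
    profs = dedupe_interior(_profiles(cup_phantom, lines, region))
    s = summarize(profs)
    t = cup_phantom.truth
    assert abs(s.max_gap - t.max_gap) < 0.05
    assert abs(s.max_step_off - t.max_step_off) < 0.05


# ---------------------------------------------------------------------------
# 2D slice emulation


def _single_point_profile(d, n, pos=(0.0, 0.0, 0.0)):
    line = FractureLine(points=np.array([pos, np.add(pos, (1e-3, 0, 0))]),
                        fragment_id="a", adjacent_fragment_id="b")
    region = PlanarPatchRegion(plane=Plane(point=(0, 0, 0), normal=n))
    prof = displacement_profile(
        line, RigidTransform(translation=d), RigidTransform.identity(), region)
    return prof


def test_slice2d_displacement_along_stack_axis_vanishes():
    """Gap purely along the slice-stack axis is invisible in-plane."""
    prof = _single_point_profile((0, 0, 3.0), (0, 1, 0))  # gap 3 along z
    gap2, step2 = slice_2d_measurement([prof], axis="axial")
    assert gap2 == pytest.approx(0.0, abs=1e-9)


def test_slice2d_in_plane_displacement_fully_seen():
    prof = _single_point_profile((3.0, 4.0, 0.0), (1, 0, 0))
    gap2, step2 = slice_2d_measurement([prof], axis="axial")
    assert np.hypot(gap2, step2) == pytest.approx(5.0)


def test_slice2d_oblique_underestimates():
    """(0,3,4) under axial slicing: only the in-plane 3 mm remains."""
    prof = _single_point_profile((0.0, 3.0, 4.0), (0, 1, 0))
    gap2, step2 = slice_2d_measurement([prof], axis="axial")
    assert np.hypot(gap2, step2) == pytest.approx(3.0)
    assert np.hypot(gap2, step2) < 5.0


@pytest.mark.parametrize("axis", ["axial", "coronal", "sagittal"])
def test_slice2d_never_exceeds_3d(cup_phantom, region, axis):
    lines = extract_fracture_lines(_reduced_set(cup_phantom), region,
                                   cup_phantom.template)
    profs = dedupe_interior(_profiles(cup_phantom, lines, region))
    s3 = summarize(profs)
    gap2, step2 = slice_2d_measurement(profs, axis=axis)
    assert gap2 <= s3.max_gap + 1e-9
    assert step2 <= s3.max_step_off + 1e-9


def test_slice2d_rejects_bad_axis():
    with pytest.raises(ValueError):
        slice_2d_measurement([], axis="oblique")
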