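"""One-call end-to-end analysis: inputs -> reduction -> metrics -> report.

Stages: (1) obtain per-fragment meshes and the intact contralateral side
(from files, from a CT-like volume via segmentation, or from the built-in
phantom generator), (2) mirror the intact side and virtually reduce the
fragments against it, (3) extract fracture lines in reduced pose and measure
step-off/gap profiles, (4) project the total gap area in the standardized
landmark view, (5) emulate the conventional 2D slice reading, (6) grade the
result.  The report is deterministic: identical configuration and inputs
produce byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from typing import Optional

from . import __version__
from .config import Config, DEFAULT
from .gaparea import standard_view, total_gap_area
from .geometry import Plane
from .grading import grade_reduction
from .io import (FragmentSet, MeasurementReport, SchemaError,
                 read_fragment_dir, read_landmarks, read_mesh)
from .metrics import (SphericalCupRegion, dedupe_interior, displacement_profile,
                      extract_fracture_lines, slice_2d_measurement, summarize)
from .reduction import build_mirror_template, match_pre_to_post, reduce_fragments

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "phantom_seed", "phantom_sectors", "make_post", "pre_dir", "intact_mesh",
    "post_model", "landmarks", "symmetry_plane_point", "symmetry_plane_normal",
    "midline_hint", "hu_threshold", "rms_max", "resample_step", "raster_step",
    "adjacency_tol", "sphere_band", "slice_thickness", "criteria", "seed",
    "log_level", "include_peripheral",
}
_POSITIVE = ("hu_threshold", "rms_max", "resample_step", "raster_step",
             "adjacency_tol", "sphere_band", "slice_thickness")


@dataclass
class PipelineConfig:
    """Validated configuration of one analysis run."""

    # input: either a phantom seed or file paths
    phantom_seed: Optional[int] = None
    phantom_sectors: tuple = (0.0, 180.0)
    make_post: bool = True
    pre_dir: Optional[str] = None
    intact_mesh: Optional[str] = None
    post_model: Optional[str] = None
    landmarks: Optional[str] = None
    symmetry_plane_point: tuple = (0.0, 0.0, 0.0)
    symmetry_plane_normal: tuple = (1.0, 0.0, 0.0)
    midline_hint: tuple = (0.0, 0.0, 0.0)
    # thresholds
    hu_threshold: float = DEFAULT.hu_threshold
    rms_max: float = DEFAULT.rms_max
    resample_step: float = DEFAULT.resample_step
    raster_step: float = DEFAULT.raster_step
    adjacency_tol: float = DEFAULT.adjacency_tol
    sphere_band: float = DEFAULT.sphere_band
    slice_thickness: float = DEFAULT.slice_thickness
    include_peripheral: bool = False
    criteria: str = "both"   # {matta, 3dct, both}
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        for key in _POSITIVE:
            if getattr(self, key) <= 0:
                raise SchemaError(f"config field {key!r} must be positive")
        if self.criteria not in ("matta", "3dct", "both"):
            raise SchemaError("criteria must be one of: matta, 3dct, both")
        if self.phantom_seed is None and (self.pre_dir is None or self.intact_mesh is None):
            raise SchemaError("either phantom_seed or pre_dir + intact_mesh is required")

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        unknown = set(doc) - _KNOWN_KEYS
        if unknown:
            raise SchemaError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        doc = dict(doc)
        for key in ("phantom_sectors", "symmetry_plane_point",
                    "symmetry_plane_normal", "midline_hint"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_config(self) -> Config:
        return DEFAULT.with_(
            hu_threshold=self.hu_threshold, rms_max=self.rms_max,
            resample_step=self.resample_step, raster_step=self.raster_step,
            adjacency_tol=self.adjacency_tol, sphere_band=self.sphere_band,
            slice_thickness=self.slice_thickness, seed=self.seed,
        )

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and offending input."""

    stage: str
    message: str

    def __str__(self):
        return f"[{self.stage}] {self.message}"


def _measure_state(reduced, poses, region, template, landmarks, cfg, pc, state):
    """Summaries + gap area + 2D emulation for one displaced state.

    ``reduced`` holds the fragments in their (shared) virtually reduced
    pose; ``poses`` maps fragment id -> RigidTransform(reduced -> displaced
    state).
    """
    lines = extract_fracture_lines(reduced, region, template, cfg)
    if not lines:
        log.info("%s: no fracture lines found", state)
        metrics = {
            "max_step_off_3d": 0.0, "mean_step_off_3d": 0.0,
            "max_gap_3d": 0.0, "mean_gap_3d": 0.0, "total_gap_area_mm2": 0.0,
            "max_gap_2d": 0.0, "max_step_off_2d": 0.0, "n_fracture_lines": 0,
        }
        return metrics
    profiles = [
        displacement_profile(
            ln, poses[ln.fragment_id],
            poses[ln.adjacent_fragment_id] if ln.adjacent_fragment_id else None,
            region,
        )
        for ln in lines
    ]
    unique = dedupe_interior(profiles)
    summary = summarize(unique, state=state)
    view = standard_view(landmarks, pc.midline_hint)
    area = total_gap_area(unique, view, raster_step=cfg.raster_step,
                          include_peripheral=pc.include_peripheral)
    per_axis = {
        ax: slice_2d_measurement(unique, axis=ax, slice_thickness=cfg.slice_thickness)
        for ax in ("axial", "coronal", "sagittal")
    }
    return {
        "max_step_off_3d": summary.max_step_off,
        "mean_step_off_3d": summary.mean_step_off,
        "max_gap_3d": summary.max_gap,
        "mean_gap_3d": summary.mean_gap,
        "total_gap_area_mm2": area,
        "max_gap_2d": max(v[0] for v in per_axis.values()),
        "max_step_off_2d": max(v[1] for v in per_axis.values()),
        "gap_2d_per_axis": {ax: v[0] for ax, v in per_axis.items()},
        "step_off_2d_per_axis": {ax: v[1] for ax, v in per_axis.items()},
        "n_fracture_lines": len(unique),
    }


def run_pipeline(pc: PipelineConfig) -> MeasurementReport:
    """Execute the full analysis described by ``pc``."""
    cfg = pc.to_config()
    # ---- inputs -----------------------------------------------------------
    try:
        if pc.phantom_seed is not None:
            from .phantom import PhantomSpec, make_phantom

            ph = make_phantom(
                PhantomSpec(seed=pc.phantom_seed,
                            sector_azimuths_deg=tuple(pc.phantom_sectors),
                            make_post=pc.make_post)
            )
            pre, intact, landmarks = ph.pre, ph.intact, ph.landmarks
            post_model = ph.post_model
            plane = ph.symmetry_plane
        else:
            pre = read_fragment_dir(pc.pre_dir, source="pre")
            intact = read_mesh(pc.intact_mesh)
            landmarks = read_landmarks(pc.landmarks) if pc.landmarks else None
            post_model = read_mesh(pc.post_model) if pc.post_model else None
            plane = Plane(point=pc.symmetry_plane_point,
                          normal=pc.symmetry_plane_normal)
        if landmarks is None:
            raise SchemaError("landmarks are required for the gap-area view")
    except (OSError, ValueError) as exc:
        raise StageError("inputs", str(exc)) from exc

    # ---- virtual reduction ------------------------------------------------
    try:
        template = build_mirror_template(intact, plane)
        reduction = reduce_fragments(pre, template, cfg)
        region = SphericalCupRegion.fit(template, band=cfg.sphere_band)
    except ValueError as exc:
        raise StageError("reduction", str(exc)) from exc

    poses_pre = {fid: reduction.displaced_pose(fid) for fid in pre.fragment_ids}
    reduced_meshes = []
    for fid, mesh in pre:
        rm = mesh.copy()
        rm.apply_transform(reduction.transforms[fid].to_matrix())
        rm.metadata["fragment_id"] = fid
        reduced_meshes.append(rm)
    reduced = FragmentSet(meshes=reduced_meshes,
                          fragment_ids=list(pre.fragment_ids), source="reduced")
    states = {"pre": _measure_state(reduced, poses_pre, region, template,
                                    landmarks, cfg, pc, "pre")}
    states["pre"]["registration_rms_mm"] = {k: round(v, 4)
                                            for k, v in reduction.rms.items()}
    states["pre"]["unreduced_fragments"] = sorted(reduction.unreduced)

    # ---- postoperative state ---------------------------------------------
    if post_model is not None:
        try:
            match = match_pre_to_post(pre, post_model, reduction, cfg)
        except ValueError as exc:
            raise StageError("post-matching", str(exc)) from exc
        poses_post = {
            # reduced -> post = (pre displaced -> post) o (reduced -> pre displaced)
            fid: match.transforms[fid].compose(poses_pre[fid])
            for fid in pre.fragment_ids
        }
        states["post"] = _measure_state(reduced, poses_post, region, template,
                                        landmarks, cfg, pc, "post")
        states["post"]["unmatched_fragments"] = sorted(match.unreduced)

    # ---- grading ----------------------------------------------------------
    grading = {}
    if "post" in states:
        post = states["post"]
        result = grade_reduction(
            post_max_gap=post["max_gap_3d"],
            post_max_step=post["max_step_off_3d"],
            post_area=post["total_gap_area_mm2"],
            pre_means={"mean_gap": states["pre"]["mean_gap_3d"],
                       "mean_step_off": states["pre"]["mean_step_off_3d"],
                       "total_gap_area": states["pre"]["total_gap_area_mm2"]},
            post_means={"mean_gap": post["mean_gap_3d"],
                        "mean_step_off": post["mean_step_off_3d"],
                        "total_gap_area": post["total_gap_area_mm2"]},
        )
        full = result.as_dict()
        if pc.criteria == "matta":
            full.pop("criteria_3dct")
        elif pc.criteria == "3dct":
            full = {k: v for k, v in full.items() if not k.startswith("matta")}
        grading = full

    report = MeasurementReport(
        states=states,
        grading=grading,
        provenance={
            "config": asdict(pc),
            "config_digest": pc.digest(),
            "seed": pc.seed,
            "version": __version__,
        },
    )
    return report
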