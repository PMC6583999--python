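"""Readers and writers for meshes, volumes, landmarks, fracture lines and reports.

Interchange conventions
-----------------------
* Meshes are STL (binary or ASCII) or PLY, assumed to be in **millimetres**
  (STL carries no units; this assumption is logged at load time).
* Volumes are NIfTI-1; voxel values are Hounsfield units and the affine maps
  index to world millimetres.
* Landmarks and fracture lines are JSON documents that declare
  ``"units": "mm"`` and ``"space": "LPS"`` explicitly; a mismatch is refused
  rather than silently converted.
* Reports are JSON (full structure) and CSV (one row per state/metric).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .geometry import as_point

log = logging.getLogger(__name__)

#: landmark names required for the standardized gap-area view: the anterior
#: inferior iliac spine, the inferolateral-most point of the obturator
#: foramen, and the most prominent point of the superior pubic ramus.
REQUIRED_LANDMARKS = ("aiis", "foramen_inferolateral", "ramus_superior_prominence")


class FormatError(ValueError):
    """A file failed to parse or violates its declared schema."""


class SchemaError(FormatError):
    """A structurally valid document is missing required content."""


# ---------------------------------------------------------------------------
# meshes


def clean_mesh(mesh: trimesh.Trimesh, merge_tol: float = 1e-6) -> trimesh.Trimesh:
    """Merge duplicate vertices (within ``merge_tol`` mm) and drop degenerate faces."""
    digits = max(0, int(round(-np.log10(merge_tol))))
    mesh.merge_vertices(digits_vertex=digits)
    ok = mesh.nondegenerate_faces()
    if not ok.all():
        mesh.update_faces(ok)
    mesh.remove_unreferenced_vertices()
    return mesh


def read_mesh(path, fragment_id: Optional[str] = None) -> trimesh.Trimesh:
    """Load an STL/PLY surface mesh (mm assumed) and clean it.

    The fragment label is stored in ``mesh.metadata['fragment_id']``.
    """
    path = Path(path)
    if path.suffix.lower() not in (".stl", ".ply"):
        raise FormatError(f"{path}: unsupported mesh format {path.suffix!r} (STL/PLY only)")
    try:
        mesh = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise FormatError(f"{path}: failed to parse mesh: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) == 0:
        raise FormatError(f"{path}: no triangle geometry found")
    log.info("loaded %s: %d vertices (units assumed mm)", path.name, len(mesh.vertices))
    clean_mesh(mesh)
    mesh.metadata["fragment_id"] = fragment_id if fragment_id is not None else path.stem
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    path = Path(path)
    mesh.export(str(path))


@dataclass
class FragmentSet:
    """A collection of per-fragment surface meshes for one state."""

    meshes: list
    fragment_ids: list
    source: str = "pre"  # {pre, post, intact}

    def __post_init__(self):
        if len(self.meshes) != len(self.fragment_ids):
            raise ValueError("one fragment_id per mesh required")
        if len(set(self.fragment_ids)) != len(self.fragment_ids):
            raise ValueError("fragment_ids must be unique")
        for fid, m in zip(self.fragment_ids, self.meshes):
            if len(m.vertices) == 0:
                raise ValueError(f"fragment {fid!r} has an empty mesh")

    def __len__(self):
        return len(self.meshes)

    def __iter__(self):
        return iter(zip(self.fragment_ids, self.meshes))

    def mesh(self, fragment_id):
        return self.meshes[self.fragment_ids.index(fragment_id)]


def read_fragment_dir(directory, source: str = "pre") -> FragmentSet:
    """Load every STL/PLY in a directory as one fragment each (sorted by name)."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".stl", ".ply"))
    if not paths:
        raise FormatError(f"{directory}: no STL/PLY files found")
    meshes = [read_mesh(p) for p in paths]
    return FragmentSet(meshes=meshes, fragment_ids=[p.stem for p in paths], source=source)


# ---------------------------------------------------------------------------
# volumes


@dataclass
class VoxelVolume:
    """Scalar CT-like volume (HU) with voxel spacing and index->world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3D, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if np.any(self.spacing <= 0):
            raise FormatError("voxel spacing must be positive")
        if self.spacing.max() > 2.0 + 1e-9:
            log.warning(
                "slice spacing %.2f mm exceeds the 2 mm acquisition maximum; "
                "measurements may be degraded", self.spacing.max()
            )

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def index_to_world(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if out.shape[0] == 1 and np.asarray(ijk).ndim == 1 else out


def read_volume(path) -> VoxelVolume:
    """Load a 3D NIfTI volume, honouring its affine (world mm)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: failed to parse NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D scalar volume, got shape {data.shape}")
    if img.affine is None:
        raise FormatError(f"{path}: missing affine")
    return VoxelVolume(data=np.asarray(data, dtype=float), affine=img.affine)


def write_volume(vol: VoxelVolume, path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))


# ---------------------------------------------------------------------------
# landmarks


@dataclass
class LandmarkSet:
    """Named anatomical points (mm); the three gap-area landmarks are required."""

    points: dict

    def __post_init__(self):
        self.points = {k: as_point(v) for k, v in self.points.items()}

    def require_view_landmarks(self):
        missing = [k for k in REQUIRED_LANDMARKS if k not in self.points]
        if missing:
            raise SchemaError(f"missing required landmark(s): {', '.join(missing)}")
        pts = [self.points[k] for k in REQUIRED_LANDMARKS]
        for i in range(3):
            for j in range(i + 1, 3):
                d = np.linalg.norm(pts[i] - pts[j])
                if d <= 5.0:
                    raise SchemaError(
                        f"landmarks {REQUIRED_LANDMARKS[i]!r} and {REQUIRED_LANDMARKS[j]!r} "
                        f"are only {d:.2f} mm apart (must exceed 5 mm)"
                    )
        return [self.points[k] for k in REQUIRED_LANDMARKS]

    def __getitem__(self, name):
        return self.points[name]


def _check_header(doc: dict, path) -> None:
    if doc.get("units") != "mm":
        raise SchemaError(f"{path}: units must be declared as 'mm' (got {doc.get('units')!r})")
    if doc.get("space") != "LPS":
        raise SchemaError(f"{path}: space must be declared as 'LPS' (got {doc.get('space')!r})")


def read_landmarks(path) -> LandmarkSet:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON at char {exc.pos}: {exc.msg}") from exc
    _check_header(doc, path)
    if "points" not in doc or not isinstance(doc["points"], dict):
        raise SchemaError(f"{path}: missing 'points' mapping")
    lm = LandmarkSet(points=doc["points"])
    lm.require_view_landmarks()
    return lm


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    doc = {
        "units": "mm",
        "space": "LPS",
        "points": {k: list(map(float, v)) for k, v in landmarks.points.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# fracture lines (the FractureLine type itself lives in fract3d.metrics)


def read_fracture_lines(path):
    """Load externally annotated fracture polylines (JSON)."""
    from .metrics import FractureLine

    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON at char {exc.pos}: {exc.msg}") from exc
    _check_header(doc, path)
    if "lines" not in doc:
        raise SchemaError(f"{path}: missing 'lines' array")
    lines = []
    for i, rec in enumerate(doc["lines"]):
        for key in ("fragment_id", "points"):
            if key not in rec:
                raise SchemaError(f"{path}: line {i} missing {key!r}")
        pts = np.asarray(rec["points"], dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise SchemaError(f"{path}: line {i} needs >= 2 points of 3 coordinates")
        lines.append(
            FractureLine(
                points=pts,
                fragment_id=rec["fragment_id"],
                adjacent_fragment_id=rec.get("adjacent_fragment_id"),
                articular=bool(rec.get("articular", True)),
            )
        )
    return lines


def write_fracture_lines(lines, path) -> None:
    doc = {
        "units": "mm",
        "space": "LPS",
        "lines": [
            {
                "fragment_id": ln.fragment_id,
                "adjacent_fragment_id": ln.adjacent_fragment_id,
                "articular": bool(ln.articular),
                "points": np.asarray(ln.points, dtype=float).tolist(),
            }
            for ln in lines
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# measurement report


@dataclass
class MeasurementReport:
    """Full pipeline output: per-state summaries, gap area, grading, provenance."""

    states: dict = field(default_factory=dict)  # state -> metric -> value
    grading: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "states": self.states,
            "grading": self.grading,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True, allow_nan=False)

    @classmethod
    def from_json(cls, text: str) -> "MeasurementReport":
        doc = json.loads(text)
        return cls(
            states=doc.get("states", {}),
            grading=doc.get("grading", {}),
            provenance=doc.get("provenance", {}),
        )


def write_report(report: MeasurementReport, json_path=None, csv_path=None) -> None:
    """Write a report as JSON (full) and/or CSV (state x metric rows)."""
    if json_path is not None:
        Path(json_path).write_text(report.to_json())
    if csv_path is not None:
        rows = [
            {"state": state, "metric": metric, "value": value}
            for state, metrics in sorted(report.states.items())
            for metric, value in sorted(metrics.items())
            if np.isscalar(value) or isinstance(value, (int, float))
        ]
        pd.DataFrame(rows, columns=["state", "metric", "value"]).to_csv(csv_path, index=False)


def read_report_csv(csv_path) -> dict:
    df = pd.read_csv(csv_path)
    out: dict = {}
    for _, row in df.iterrows():
        out.setdefault(row["state"], {})[row["metric"]] = float(row["value"])
    return out
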