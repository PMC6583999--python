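"""Elementary 3D types and the displacement decomposition.

Points and vectors are ``numpy`` arrays of shape ``(3,)`` (or ``(n, 3)`` for
batches), in millimetres, right-handed.  The two quantities every other
module builds on are defined here:

* the *step-off*, the component of a fracture-line displacement
  perpendicular to the articular surface (articular incongruity), and
* the *gap*, the component tangential to the articular surface
  (fragment separation along the joint).

For a displacement vector ``d`` and unit articular normal ``n``::

    step_off = |d . n|
    gap      = || d - (d . n) n ||

so that ``step_off**2 + gap**2 == ||d||**2`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "as_point",
    "euclidean_distance",
    "decompose_displacement",
    "Plane",
    "plane_from_points",
    "RigidTransform",
    "ReflectionTransform",
    "mirror_transform",
]


def as_point(p) -> np.ndarray:
    """Coerce to a finite float array of shape (3,) or (n, 3)."""
    a = np.asarray(p, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError(f"expected 3 components, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite coordinates")
    return a


def euclidean_distance(a, b) -> float:
    """Straight-line distance between two points (mm)."""
    return float(np.linalg.norm(as_point(a) - as_point(b)))


def _check_unit(n: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    norms = np.linalg.norm(n, axis=-1)
    if not np.allclose(norms, 1.0, atol=tol):
        raise ValueError("normal must be unit length")
    return n


def decompose_displacement(d, n, signed: bool = False):
    """Split displacement ``d`` into step-off and gap w.r.t. unit normal ``n``.

    Works element-wise on ``(k, 3)`` batches.  With ``signed=True`` the
    step-off keeps the sign of ``d . n`` (positive = displaced along the
    outward articular normal, i.e. a proud fragment); summaries in this
    package always use magnitudes.

    Returns ``(step_off, gap)``.
    """
    d = as_point(d)
    n = _check_unit(as_point(n))
    dn = np.sum(d * n, axis=-1)
    tangential = d - dn[..., None] * n
    gap = np.linalg.norm(tangential, axis=-1)
    step = dn if signed else np.abs(dn)
    if d.ndim == 1:
        return float(step), float(gap)
    return step, gap


@dataclass(frozen=True)
class Plane:
    """A plane through ``point`` with unit ``normal``."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", as_point(self.point))
        n = as_point(self.normal)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValueError("degenerate plane normal")
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, pts) -> np.ndarray:
        pts = as_point(pts)
        return np.dot(pts - self.point, self.normal)


def plane_from_points(p1, p2, p3) -> Plane:
    """Plane through three non-collinear points.

    The normal is ``(p2 - p1) x (p3 - p1)`` normalized, so the point order
    fixes its orientation (right-hand rule).
    """
    p1, p2, p3 = as_point(p1), as_point(p2), as_point(p3)
    n = np.cross(p2 - p1, p3 - p1)
    span = max(np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1), 1.0)
    if np.linalg.norm(n) <= 1e-12 * span * span:
        raise ValueError("collinear points do not define a plane")
    return Plane(point=p1, normal=n)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = as_point(self.translation)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return cls(rotation=m[:3, :3], translation=m[:3, 3])

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, pts) -> np.ndarray:
        pts = as_point(pts)
        return pts @ self.rotation.T + self.translation

    def apply_vector(self, v) -> np.ndarray:
        return as_point(v) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply ``other`` first)."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(rotation=Rt, translation=-Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class ReflectionTransform:
    """Mirror across a plane; applying it twice is the identity."""

    plane: Plane

    def apply(self, pts) -> np.ndarray:
        pts = as_point(pts)
        d = np.dot(pts - self.plane.point, self.plane.normal)
        return pts - 2.0 * d[..., None] * self.plane.normal

    def apply_vector(self, v) -> np.ndarray:
        v = as_point(v)
        d = np.dot(v, self.plane.normal)
        return v - 2.0 * d[..., None] * self.plane.normal

    def to_matrix(self) -> np.ndarray:
        n = self.plane.normal
        m = np.eye(4)
        m[:3, :3] = np.eye(3) - 2.0 * np.outer(n, n)
        m[:3, 3] = 2.0 * np.dot(self.plane.point, n) * n
        return m


def mirror_transform(plane: Plane) -> ReflectionTransform:
    """Reflection across ``plane`` (the mirrored-hemipelvis template step)."""
    return ReflectionTransform(plane=plane)
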