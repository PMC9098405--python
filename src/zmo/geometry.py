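"""Rigid transforms and planes in 3D world coordinates (RAS millimetres).

These primitives carry the mirroring and fusion maps used throughout the
package.  Rotations are proper orthogonal 3x3 matrices; translations are in
millimetres.  All arrays are float64.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

_ORTHO_TOL = 1e-9


def _as_point(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (3,):
        raise ValidationError(f"expected a 3-vector, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValidationError("non-finite coordinates")
    return p


def unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValidationError("cannot normalise a near-zero vector")
    return v / n


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t``.

    ``rotation`` must be proper orthogonal (det = +1) to 1e-9; composition and
    inversion stay within the type.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValidationError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValidationError("rotation matrix is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValidationError("rotation matrix must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls,
        axis,
        angle_deg: float,
        center=None,
        translation=(0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Rotation of ``angle_deg`` about ``axis`` through ``center``,
        followed by ``translation``."""
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * unit(axis)).as_matrix()
        t = np.asarray(translation, dtype=float).copy()
        if center is not None:
            c = _as_point(center)
            t = t + c - R @ c
        return cls(R, t)

    def apply(self, points) -> np.ndarray:
        """Apply to one point (3,) or a stack of points (N, 3)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"], float), np.asarray(d["translation"], float))


@dataclass(frozen=True)
class Plane:
    """Oriented plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", _as_point(self.point))
        object.__setattr__(self, "normal", unit(self.normal))

    def signed_distance(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (p - self.point) @ self.normal

    def reflect(self, points) -> np.ndarray:
        """Mirror points across the plane (isometric involution)."""
        p = np.asarray(points, dtype=float)
        d = self.signed_distance(p)
        return p - 2.0 * np.multiply.outer(d, self.normal)

    def reflection_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world-coordinate reflection across the plane."""
        n = self.normal
        M = np.eye(4)
        M[:3, :3] = np.eye(3) - 2.0 * np.outer(n, n)
        M[:3, 3] = 2.0 * (self.point @ n) * n
        return M

    def to_dict(self) -> dict:
        return {"point": self.point.tolist(), "normal": self.normal.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Plane":
        return cls(np.asarray(d["point"], float), np.asarray(d["normal"], float))
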