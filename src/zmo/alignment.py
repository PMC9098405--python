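"""Anatomical head frame, midsagittal mirroring and rigid landmark alignment.

The head frame standardises orientation the way craniofacial planning
software does: the Frankfort horizontal (FH) plane is fitted through the
bilateral porion and orbitale landmarks, and the vertical midline (midsagittal
plane) is taken perpendicular to it, anchored at the nasion and the porion
midpoint.  Mirroring across the midsagittal plane turns the unaffected side
into the presurgical-plan object; rigid landmark alignment (Kabsch) merges
intraoperative geometry with the plan; registration verification applies the
clinical < 1 mm pointer-check rule.

Conventions: world coordinates are RAS millimetres derived from the NIfTI
affine; frame axes are x = right (midsagittal normal), y = anterior,
z = superior (FH normal).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import scipy.ndimage as ndi

from .exceptions import (
    AlignmentError,
    DegenerateFrameError,
    OrientationError,
    ValidationError,
)
from .geometry import Plane, RigidTransform, _as_point, unit

REQUIRED_LANDMARKS = (
    "porion_L",
    "porion_R",
    "orbitale_L",
    "orbitale_R",
    "nasion",
    "incisor_tip",
)

#: Frame landmarks whose L/R entries must come together; the per-side
#: optional landmarks (foramen, arch base, sutures) may legitimately appear
#: on one side only, e.g. in a plan object for the affected side.
PAIRED_STEMS = ("porion", "orbitale")

SUTURE_NAMES = ("ZM", "ZF", "IO", "ZS", "ZT")


class LandmarkSet:
    """Named anatomical points in 3D world coordinates (mm).

    Thin mapping wrapper that validates finiteness and left/right pairing at
    construction.  Landmark names follow ``<stem>_L`` / ``<stem>_R`` for
    bilateral structures.
    """

    def __init__(self, points: Mapping[str, Iterable[float]]):
        self._points: dict[str, np.ndarray] = {
            str(k): _as_point(v) for k, v in points.items()
        }
        for stem in PAIRED_STEMS:
            left, right = f"{stem}_L" in self._points, f"{stem}_R" in self._points
            if left != right:
                raise ValidationError(
                    f"paired landmark {stem!r} present on one side only"
                )
        if "porion_L" in self._points and "porion_R" in self._points:
            if np.allclose(self._points["porion_L"], self._points["porion_R"]):
                raise ValidationError("porion_L and porion_R coincide")

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self._points[name]
        except KeyError:
            raise ValidationError(f"missing landmark {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._points

    def __len__(self) -> int:
        return len(self._points)

    def __iter__(self):
        return iter(self._points)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._points)

    def require(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self._points]
        if missing:
            raise ValidationError(f"missing required landmarks: {missing}")

    def subset(self, names: Iterable[str]) -> "LandmarkSet":
        return LandmarkSet({n: self[n] for n in names})

    def transform(self, t: RigidTransform) -> "LandmarkSet":
        return LandmarkSet({n: t.apply(p) for n, p in self._points.items()})

    def as_array(self, names: Iterable[str]) -> np.ndarray:
        return np.stack([self[n] for n in names])

    def to_dict(self) -> dict[str, list[float]]:
        return {n: p.tolist() for n, p in sorted(self._points.items())}

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[float]]) -> "LandmarkSet":
        return cls(d)


@dataclass(frozen=True)
class HeadFrame:
    """Orthonormal anatomical frame: FH plane + vertical midline.

    ``axes`` rows are the world directions of the frame axes
    (x right, y anterior, z superior); ``world_to_frame`` maps world
    coordinates into frame coordinates with the origin on the midsagittal
    plane at the porion-midpoint level.
    """

    origin: np.ndarray
    axes: np.ndarray  # rows: x, y, z
    fh_plane: Plane
    midsagittal_plane: Plane
    world_to_frame: RigidTransform
    fh_residual_mm: float = 0.0

    def __post_init__(self):
        A = np.asarray(self.axes, dtype=float)
        if not np.allclose(A @ A.T, np.eye(3), atol=1e-8):
            raise ValidationError("frame axes are not orthonormal")
        if abs(self.midsagittal_plane.normal @ self.fh_plane.normal) > 1e-8:
            raise ValidationError("midsagittal plane not perpendicular to FH plane")

    def to_frame(self, points) -> np.ndarray:
        return self.world_to_frame.apply(points)

    def to_world(self, points) -> np.ndarray:
        return self.world_to_frame.inverse().apply(points)

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "axes": np.asarray(self.axes).tolist(),
            "fh_plane": self.fh_plane.to_dict(),
            "midsagittal_plane": self.midsagittal_plane.to_dict(),
            "world_to_frame": self.world_to_frame.to_dict(),
            "fh_residual_mm": float(self.fh_residual_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HeadFrame":
        return cls(
            origin=np.asarray(d["origin"], float),
            axes=np.asarray(d["axes"], float),
            fh_plane=Plane.from_dict(d["fh_plane"]),
            midsagittal_plane=Plane.from_dict(d["midsagittal_plane"]),
            world_to_frame=RigidTransform.from_dict(d["world_to_frame"]),
            fh_residual_mm=float(d.get("fh_residual_mm", 0.0)),
        )


def _fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Least-squares plane. Returns (centroid, normal, residual rms, planarity)."""
    c = points.mean(axis=0)
    q = points - c
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    normal = vt[-1]
    residual = float(np.sqrt(np.mean((q @ normal) ** 2)))
    return c, normal, residual, float(s[-2])


def compute_head_frame(landmarks: LandmarkSet) -> HeadFrame:
    """Construct the FH-plane / vertical-midline head frame from landmarks.

    The FH plane is the least-squares plane through the four porion/orbitale
    landmarks.  The superior direction is the FH normal signed so the upper
    incisor tip lies below the plane; the right direction is the porion
    left-to-right vector projected into the FH plane; anterior completes the
    right-handed triple and must point towards the nasion (otherwise the
    landmark labels are inconsistent and an :class:`OrientationError` is
    raised rather than guessing).  The midsagittal plane has the right axis as
    normal and is anchored halfway between the nasion and the porion midpoint
    (their mean offset along that axis).
    """
    landmarks.require(REQUIRED_LANDMARKS)
    fh_pts = landmarks.as_array(
        ["porion_L", "porion_R", "orbitale_L", "orbitale_R"]
    )
    centroid, normal, residual, spread = _fit_plane(fh_pts)
    if spread < 1e-6:
        raise DegenerateFrameError("FH landmarks are collinear")

    incisor = landmarks["incisor_tip"]
    z = normal if (incisor - centroid) @ normal < 0 else -normal
    if abs((incisor - centroid) @ z) < 1e-9:
        raise DegenerateFrameError("incisor tip lies on the FH plane; cannot orient")

    lr = landmarks["porion_R"] - landmarks["porion_L"]
    x_in_plane = lr - (lr @ z) * z
    if np.linalg.norm(x_in_plane) < 1e-9:
        raise DegenerateFrameError("porion axis perpendicular to FH plane")
    x = unit(x_in_plane)
    y = np.cross(z, x)

    porion_mid = 0.5 * (landmarks["porion_L"] + landmarks["porion_R"])
    if (landmarks["nasion"] - porion_mid) @ y <= 0:
        raise OrientationError(
            "nasion is not anterior of the porion midpoint; "
            "left/right landmark labels appear swapped"
        )

    offset = 0.5 * (landmarks["nasion"] @ x + porion_mid @ x)
    origin = porion_mid + (offset - porion_mid @ x) * x
    axes = np.stack([x, y, z])
    world_to_frame = RigidTransform(axes, -axes @ origin)
    return HeadFrame(
        origin=origin,
        axes=axes,
        fh_plane=Plane(centroid, z),
        midsagittal_plane=Plane(origin, x),
        world_to_frame=world_to_frame,
        fh_residual_mm=residual,
    )


def mirror_points(points, frame: HeadFrame) -> np.ndarray:
    """Reflect world points across the frame's midsagittal plane."""
    return frame.midsagittal_plane.reflect(points)


def mirror_landmarks(landmarks: LandmarkSet, frame: HeadFrame) -> LandmarkSet:
    """Reflect every landmark; names are kept (no L/R renaming)."""
    return LandmarkSet(
        {n: frame.midsagittal_plane.reflect(landmarks[n]) for n in landmarks}
    )


def mirror_mask(mask: np.ndarray, affine: np.ndarray, frame: HeadFrame) -> np.ndarray:
    """Reflect a label mask across the midsagittal plane.

    The reflected volume is resampled back onto the source grid with
    nearest-neighbour interpolation, so labels stay integral.
    """
    mask = np.asarray(mask)
    A = np.asarray(affine, dtype=float)
    M_world = frame.midsagittal_plane.reflection_matrix()
    M_vox = np.linalg.inv(A) @ M_world @ A  # involution in voxel space
    out = ndi.affine_transform(
        mask,
        matrix=M_vox[:3, :3],
        offset=M_vox[:3, 3],
        order=0,
        mode="constant",
        cval=0,
        output=mask.dtype,
    )
    return out


def rigid_align(
    moving: LandmarkSet, fixed: LandmarkSet, names: Iterable[str]
) -> tuple[RigidTransform, float]:
    """Least-squares rigid (no scaling) alignment of named landmark pairs.

    Returns the transform mapping ``moving`` onto ``fixed`` and the post-fit
    RMSD in millimetres (Kabsch / orthogonal Procrustes with the proper-
    rotation determinant correction).
    """
    names = list(names)
    if len(names) < 3:
        raise AlignmentError("rigid alignment needs at least 3 shared landmarks")
    P = moving.as_array(names)
    Q = fixed.as_array(names)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    # collinearity check: rank of the centred moving set
    if np.linalg.matrix_rank(P0, tol=1e-8 * max(1.0, np.abs(P0).max())) < 2:
        raise AlignmentError("landmarks are collinear; rotation is under-determined")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(P) - Q) ** 2, axis=1))))
    return transform, rmsd


@dataclass(frozen=True)
class RegistrationCheck:
    passed: bool
    distance_mm: float
    tol_mm: float


def verify_registration(
    image_landmark, probe_landmark, tol_mm: float = 1.0
) -> RegistrationCheck:
    """Clinical pointer check: pass iff the probe lands < ``tol_mm`` from the
    imaged landmark (default 1 mm acceptance rule)."""
    d = float(np.linalg.norm(_as_point(image_landmark) - _as_point(probe_landmark)))
    return RegistrationCheck(passed=d < tol_mm, distance_mm=d, tol_mm=float(tol_mm))
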