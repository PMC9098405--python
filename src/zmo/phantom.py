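"""Synthetic cranial phantom: label volumes + landmarks with known truth.

The phantom emulates the geometry the downstream metrics need from a facial
CT, not the CT itself: two thin zygoma shells (spherical-cap patches whose
axial cross-section is a circular arc centred on the arch-base/midline
intersection point), two orbital cavities (half-ellipsoids, open anteriorly
at a rim plane, with a flat floor plane and a medial-wall half-space meeting
along an anterior-posterior edge so coronal sections show a transition-zone
corner with a prescribed dihedral angle), and the full landmark set (porion,
orbitale, nasion, incisor tip, infraorbital foramina, arch bases, five suture
points per side, prominence points).

One side is designated affected: its zygoma fragment (shell + suture
landmarks + prominence) is moved by a known rigid transform, and its orbital
cavity is scaled about its centre so the volume exceeds the unaffected side
by a requested increment (scaling makes the increment exact up to the
voxelisation of the output grid; the base volume is measured once on a fine
auxiliary grid).  The unaffected side is the exact mirror image of the
affected side's pre-displacement geometry, so an identity displacement with
zero increment yields a bilaterally mirror-symmetric phantom.

Everything is deterministic given the spec: landmark jitter (if any) is drawn
from a generator seeded by ``spec.seed`` and applied only after the ground
truth has been captured from the noiseless geometry.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .alignment import SUTURE_NAMES, LandmarkSet
from .exceptions import PhantomSizingError, ValidationError
from .geometry import RigidTransform

# ---------------------------------------------------------------------------
# Fixed phantom geometry (right side; the left side is the x -> -x mirror).
# All quantities in world millimetres, RAS axes, head centred on the origin.
# ---------------------------------------------------------------------------

#: sphere centre of the zygoma shells == arch-base line / midline intersection
ZYG_CENTER = np.array([0.0, -55.0, 0.0])
ZYG_R_IN = 56.0
ZYG_R_OUT = 59.0
ZYG_AZ_MAX_DEG = 63.0  # azimuthal sector [0, max] measured from +x towards +y
ZYG_Z_HALF = 12.0      # vertical cap extent |z| <= this
ZYG_PROMINENCE_AZ_DEG = 45.0

#: orbital cavity (right): centre, semi-axes, corner offsets (fractions)
#: the rim-plane depth is kept off the voxel-centre layers of the standard
#: 1.0 / 0.5 / 0.25 mm grids so flat faces are not half-counted
ORBIT_CENTER = np.array([31.0, 27.3, 10.0])
ORBIT_AXES = np.array([17.0, 24.0, 24.0])  # a (lateral), b (depth), c (height)
CORNER_X_FRAC = 0.45  # corner sits this fraction of a medial of the centre
CORNER_Z_FRAC = 0.30  # and this fraction of c below the centre

#: midline / FH landmarks
FIXED_LANDMARKS = {
    "porion_R": (60.0, -45.0, 0.0),
    "porion_L": (-60.0, -45.0, 0.0),
    "orbitale_R": (36.0, 32.0, 0.0),
    "orbitale_L": (-36.0, 32.0, 0.0),
    "nasion": (0.0, 42.0, 12.0),
    "incisor_tip": (0.0, 46.0, -34.0),
}

INFRAORBITAL_FORAMEN_R = np.array([28.0, 30.0, 2.0])

#: suture landmark positions on the shell mid-surface, (azimuth deg, elevation deg)
SUTURE_ANGLES = {
    "ZM": (55.0, -8.0),
    "ZF": (50.0, 11.0),
    "IO": (60.0, 5.0),
    "ZS": (42.0, 9.0),
    "ZT": (8.0, -3.0),
}

LABELS = {"zygoma_L": 1, "zygoma_R": 2, "orbit_L": 3, "orbit_R": 4}

_GRID_HALF_EXTENT = (80.0, 80.0, 60.0)  # mm covered on each side of the origin


def default_grid_shape(voxel_spacing_mm) -> tuple[int, int, int]:
    """Odd-sized grid centred on the origin covering the standard head box."""
    sp = np.asarray(voxel_spacing_mm, dtype=float)
    return tuple(int(2 * math.floor(h / s) + 1) for h, s in zip(_GRID_HALF_EXTENT, sp))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case.

    ``zygoma_rotation_deg`` rotates the affected fragment about
    ``zygoma_rotation_axis`` through the fragment's prominence point, then
    ``zygoma_translation_mm`` is added; ``orbital_volume_increment_mm3``
    inflates the affected cavity by that many cubic millimetres.
    ``buttress_angles_deg`` are the (anterior, middle, posterior) transition-
    zone dihedral angles; the affected side may override them.
    """

    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grid_shape: tuple[int, int, int] | None = None
    side_affected: str = "left"
    zygoma_rotation_deg: float = 0.0
    zygoma_rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    zygoma_translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orbital_volume_increment_mm3: float = 0.0
    buttress_angles_deg: tuple[float, float, float] = (135.0, 135.0, 135.0)
    affected_buttress_angles_deg: tuple[float, float, float] | None = None
    noise_sd_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValidationError("voxel spacing components must be positive")
        if self.side_affected not in ("left", "right"):
            raise ValidationError("side_affected must be 'left' or 'right'")
        if self.orbital_volume_increment_mm3 < 0:
            raise ValidationError("orbital volume increment must be non-negative")
        if self.noise_sd_mm < 0:
            raise ValidationError("noise_sd_mm must be non-negative")

    @property
    def resolved_grid_shape(self) -> tuple[int, int, int]:
        if self.grid_shape is not None:
            return tuple(int(n) for n in self.grid_shape)
        return default_grid_shape(self.voxel_spacing_mm)

    def affine(self) -> np.ndarray:
        sp = np.asarray(self.voxel_spacing_mm, float)
        shape = np.asarray(self.resolved_grid_shape, float)
        A = np.eye(4)
        A[:3, :3] = np.diag(sp)
        A[:3, 3] = -(shape - 1) / 2.0 * sp
        return A


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth captured from the noiseless analytic geometry."""

    applied_transform: RigidTransform
    true_suture_gaps_mm: dict[str, float]
    true_volume_increment_mm3: float
    true_buttress_angles_deg: dict[str, tuple[float, float, float]]
    base_cavity_volume_mm3: float
    side_affected: str

    def to_dict(self) -> dict:
        return {
            "applied_transform": self.applied_transform.to_dict(),
            "true_suture_gaps_mm": dict(self.true_suture_gaps_mm),
            "true_volume_increment_mm3": self.true_volume_increment_mm3,
            "true_buttress_angles_deg": {
                k: list(v) for k, v in self.true_buttress_angles_deg.items()
            },
            "base_cavity_volume_mm3": self.base_cavity_volume_mm3,
            "side_affected": self.side_affected,
        }


# ---------------------------------------------------------------------------
# analytic membership predicates (vectorised over broadcastable X, Y, Z)
# ---------------------------------------------------------------------------

def _shell_membership_right(X, Y, Z):
    dx, dy, dz = X - ZYG_CENTER[0], Y - ZYG_CENTER[1], Z - ZYG_CENTER[2]
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    az = np.degrees(np.arctan2(dy, dx))
    return (
        (r >= ZYG_R_IN)
        & (r <= ZYG_R_OUT)
        & (az >= 0.0)
        & (az <= ZYG_AZ_MAX_DEG)
        & (np.abs(dz) <= ZYG_Z_HALF)
    )


def _cavity_membership_right(X, Y, Z, scale=1.0, angles_deg=(135.0, 135.0, 135.0)):
    cx, cy, cz = ORBIT_CENTER
    a, b, c = ORBIT_AXES * scale
    inside = (
        ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2
    ) <= 1.0
    inside &= Y <= cy  # anterior rim plane (open face of the cavity)
    # self-similar coronal sections: the floor line and the medial-wall line
    # scale with the local section so every section shows the same corner
    sy = np.sqrt(np.maximum(1.0 - ((Y - cy) / b) ** 2, 0.0))
    x_q = cx - CORNER_X_FRAC * a * sy
    z_q = cz - CORNER_Z_FRAC * c * sy
    inside &= Z >= z_q  # orbital floor
    # medial wall: one dihedral angle per floor third (bands along depth)
    edges = (cy - b / 3.0, cy - 2.0 * b / 3.0)
    bands = (Y > edges[0], (Y <= edges[0]) & (Y > edges[1]), Y <= edges[1])
    wall = np.zeros(np.broadcast_shapes(X.shape, Y.shape, Z.shape), dtype=bool)
    for band, alpha in zip(bands, angles_deg):
        al = math.radians(alpha)
        ok = (X - x_q) * math.sin(al) - (Z - z_q) * math.cos(al) >= 0.0
        wall |= band & ok
    return inside & wall


def _mirrored(pred, side: str):
    """Evaluate a right-side predicate on the requested side."""
    if side == "right":
        return pred
    return lambda X, Y, Z, **kw: pred(-X, Y, Z, **kw)


def _mirror_x(p: np.ndarray) -> np.ndarray:
    return np.array([-p[0], p[1], p[2]])


def _sphere_point(azimuth_deg: float, elevation_deg: float, radius: float) -> np.ndarray:
    az, el = math.radians(azimuth_deg), math.radians(elevation_deg)
    return ZYG_CENTER + radius * np.array(
        [math.cos(az) * math.cos(el), math.sin(az) * math.cos(el), math.sin(el)]
    )


def _right_side_landmarks() -> dict[str, np.ndarray]:
    mid_r = 0.5 * (ZYG_R_IN + ZYG_R_OUT)
    lm = {
        "arch_base_R": _sphere_point(0.0, 0.0, ZYG_R_OUT),
        "infraorbital_foramen_R": INFRAORBITAL_FORAMEN_R.copy(),
        "zygoma_prominence_R": _sphere_point(ZYG_PROMINENCE_AZ_DEG, 0.0, ZYG_R_OUT),
    }
    for name, (az, el) in SUTURE_ANGLES.items():
        lm[f"suture_{name}_R"] = _sphere_point(az, el, mid_r)
    return lm


def prominence_point(side: str) -> np.ndarray:
    """Pre-displacement zygomatic prominence of the given side."""
    p = _sphere_point(ZYG_PROMINENCE_AZ_DEG, 0.0, ZYG_R_OUT)
    return p if side == "right" else _mirror_x(p)


def base_cavity_volume_mm3(
    angles_deg=(135.0, 135.0, 135.0), fine_step_mm: float = 0.5
) -> float:
    """Reference cavity volume by fine-grid voxel counting (right side)."""
    cx, cy, cz = ORBIT_CENTER
    a, b, c = ORBIT_AXES
    # generous bbox; z bounded below by the floor plane
    h = fine_step_mm / 2.0  # half-step offset: avoid sampling exactly on faces
    xs = np.arange(cx - a - 2 + h, cx + a + 2, fine_step_mm)
    ys = np.arange(cy - b - 2 + h, cy + 1, fine_step_mm)
    zs = np.arange(cz - c - 2 + h, cz + c + 2, fine_step_mm)
    m = _cavity_membership_right(
        xs[:, None, None], ys[None, :, None], zs[None, None, :],
        scale=1.0, angles_deg=angles_deg,
    )
    return float(m.sum()) * fine_step_mm**3


# ---------------------------------------------------------------------------
# builder
# ---------------------------------------------------------------------------

_STRUCT_MARGIN = 10.0  # bbox margin around analytic extents, mm


def _structure_bbox(name: str, scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    if name.startswith("zygoma"):
        lo = np.array([0.0, ZYG_CENTER[1] - ZYG_R_OUT, -ZYG_Z_HALF])
        hi = np.array([ZYG_R_OUT, ZYG_CENTER[1] + ZYG_R_OUT, ZYG_Z_HALF])
    else:
        half = ORBIT_AXES * scale
        lo = ORBIT_CENTER - half
        hi = ORBIT_CENTER + half
    lo, hi = lo - _STRUCT_MARGIN, hi + _STRUCT_MARGIN
    if name.endswith("_L"):  # mirror the lateral axis only
        lo[0], hi[0] = -hi[0], -lo[0]
    return lo, hi


def _rasterize(pred, spec: PhantomSpec, bbox, out: np.ndarray, label: int, name: str):
    """Evaluate a membership predicate over its bbox and paint a label."""
    shape = spec.resolved_grid_shape
    A = spec.affine()
    sp = np.diag(A)[:3]
    origin = A[:3, 3]
    lo_idx = np.maximum(np.floor((bbox[0] - origin) / sp).astype(int), 0)
    hi_idx = np.minimum(np.ceil((bbox[1] - origin) / sp).astype(int) + 1,
                        np.asarray(shape))
    if np.any(lo_idx >= hi_idx):
        raise PhantomSizingError(name, f"structure {name!r} lies outside the grid")
    coords = [
        origin[k] + sp[k] * np.arange(lo_idx[k], hi_idx[k]) for k in range(3)
    ]
    sub = pred(
        coords[0][:, None, None], coords[1][None, :, None], coords[2][None, None, :]
    )
    if not sub.any():
        raise PhantomSizingError(name, f"structure {name!r} rasterised empty")
    region = out[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]]
    if np.any(region[sub] != 0):
        raise PhantomSizingError(name, f"structure {name!r} overlaps another label")
    region[sub] = label
    return lo_idx, hi_idx, sub


def _check_inside_grid(labels: np.ndarray, name_by_label: dict[int, str]):
    for axis in range(3):
        for idx in (0, -1):
            face = np.take(labels, idx, axis=axis)
            hit = np.unique(face[face != 0])
            if hit.size:
                raise PhantomSizingError(
                    name_by_label[int(hit[0])],
                    f"structure {name_by_label[int(hit[0])]!r} touches the grid "
                    "boundary; enlarge grid_shape",
                )


def build_phantom(spec: PhantomSpec):
    """Build (label_volume, landmarks, truth) for one synthetic case.

    Returns a ``nibabel.Nifti1Image`` with integer labels (see ``LABELS``),
    the landmark set (jittered if ``noise_sd_mm > 0``), and the
    :class:`PhantomTruth` captured from the noiseless geometry.
    """
    affected = spec.side_affected
    unaffected = "right" if affected == "left" else "left"
    aff_suffix = "_L" if affected == "left" else "_R"

    prominence = prominence_point(affected)
    transform = RigidTransform.from_axis_angle(
        spec.zygoma_rotation_axis,
        spec.zygoma_rotation_deg,
        center=prominence,
        translation=spec.zygoma_translation_mm,
    )

    # --- landmarks (noiseless) -------------------------------------------
    lm = {k: np.asarray(v, float) for k, v in FIXED_LANDMARKS.items()}
    right = _right_side_landmarks()
    lm.update(right)
    lm.update({k[:-2] + "_L": _mirror_x(v) for k, v in right.items()})

    gaps: dict[str, float] = {}
    for s in SUTURE_NAMES:
        name = f"suture_{s}{aff_suffix}"
        p = lm[name]
        moved = transform.apply(p)
        gaps[s] = float(np.linalg.norm(moved - p))
        lm[name] = moved
    lm[f"zygoma_prominence{aff_suffix}"] = transform.apply(
        lm[f"zygoma_prominence{aff_suffix}"]
    )

    # --- cavity scaling for the requested volume increment ----------------
    base_angles = tuple(float(a) for a in spec.buttress_angles_deg)
    aff_angles = tuple(
        float(a)
        for a in (spec.affected_buttress_angles_deg or spec.buttress_angles_deg)
    )
    fine = min(0.5, float(min(spec.voxel_spacing_mm)) / 2.0)
    v0 = base_cavity_volume_mm3(aff_angles, fine_step_mm=fine)
    inc = float(spec.orbital_volume_increment_mm3)
    scale = ((v0 + inc) / v0) ** (1.0 / 3.0)

    # --- rasterise ---------------------------------------------------------
    labels = np.zeros(spec.resolved_grid_shape, dtype=np.int16)
    name_by_label = {v: k for k, v in LABELS.items()}

    inv = transform.inverse()

    def displaced_shell(X, Y, Z):
        pts = np.stack(np.broadcast_arrays(X, Y, Z), axis=-1)
        back = inv.apply(pts.reshape(-1, 3)).reshape(pts.shape)
        base = _mirrored(_shell_membership_right, affected)
        return base(back[..., 0], back[..., 1], back[..., 2])

    structures = {
        f"zygoma{aff_suffix}": (
            displaced_shell,
            _structure_bbox(f"zygoma{aff_suffix}"),
        ),
        "zygoma_L" if affected == "right" else "zygoma_R": (
            _mirrored(_shell_membership_right, unaffected),
            _structure_bbox("zygoma_L" if affected == "right" else "zygoma_R"),
        ),
        f"orbit{aff_suffix}": (
            lambda X, Y, Z: _mirrored(_cavity_membership_right, affected)(
                X, Y, Z, scale=scale, angles_deg=aff_angles
            ),
            _structure_bbox(f"orbit{aff_suffix}", scale=scale),
        ),
        "orbit_L" if affected == "right" else "orbit_R": (
            lambda X, Y, Z: _mirrored(_cavity_membership_right, unaffected)(
                X, Y, Z, scale=1.0, angles_deg=base_angles
            ),
            _structure_bbox("orbit_L" if affected == "right" else "orbit_R"),
        ),
    }
    # widen the affected-zygoma bbox for the applied displacement
    disp_margin = float(np.linalg.norm(spec.zygoma_translation_mm)) + (
        abs(spec.zygoma_rotation_deg) / 180.0 * math.pi * ZYG_R_OUT
    )
    name = f"zygoma{aff_suffix}"
    lo, hi = structures[name][1]
    structures[name] = (structures[name][0], (lo - disp_margin, hi + disp_margin))

    for name, (pred, bbox) in structures.items():
        _rasterize(pred, spec, bbox, labels, LABELS[name], name)
    _check_inside_grid(labels, name_by_label)

    # --- jitter ------------------------------------------------------------
    if spec.noise_sd_mm > 0:
        rng = np.random.default_rng(spec.seed)
        for n in sorted(lm):
            lm[n] = lm[n] + rng.normal(0.0, spec.noise_sd_mm, size=3)

    truth = PhantomTruth(
        applied_transform=transform,
        true_suture_gaps_mm=gaps,
        true_volume_increment_mm3=inc,
        true_buttress_angles_deg={
            "affected": aff_angles,
            "unaffected": base_angles,
        },
        base_cavity_volume_mm3=v0,
        side_affected=affected,
    )
    img = nib.Nifti1Image(labels, spec.affine())
    return img, LandmarkSet(lm), truth


def label_mask(label_img, structure: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract one structure's binary mask and the affine from a label image."""
    if structure not in LABELS:
        raise ValidationError(f"unknown structure {structure!r}")
    data = np.asarray(label_img.dataobj)
    return (data == LABELS[structure]), np.asarray(label_img.affine, float)
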