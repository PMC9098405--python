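"""Zygoma reduction-accuracy metrics: suture displacement and deviation index.

Two families of measurements quantify how far the (pre- or postoperative)
zygoma sits from the mirrored presurgical plan:

* **2D suture displacement** — Euclidean distance between each of the five
  key suture landmarks (ZM, ZF, IO, ZS, ZT) on the actual fragment and its
  counterpart on the plan, plus their sum.
* **3D deviation index (DI)** — on an axial slice parallel to the FH plane
  through the zygomatic prominence, point O is the intersection of the
  vertical midline with the line through the bilateral zygomatic-arch bases.
  Five rays from O, evenly spaced in angle strictly between the infraorbital
  foramen and the affected arch base, intersect the actual contour at Z1–Z5
  and the plan contour at P1–P5; DI = Σ |ZiPi|.  The radial sums Σ|ZiO| and
  Σ|PiO| quantify conformance between result and plan.

All slice geometry lives in head-frame coordinates (x right, y anterior),
so the midline is the line x = 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage import measure

from .alignment import SUTURE_NAMES, HeadFrame, LandmarkSet, mirror_points
from .exceptions import (
    DegenerateSpanError,
    RayMissError,
    SliceError,
    ValidationError,
)

CONTOUR_SPACING_MM = 0.25


@dataclass(frozen=True)
class SutureDisplacement:
    """Per-suture gap (mm) between actual and plan landmark positions."""

    gaps_mm: dict[str, float]
    sum_mm: float

    def __post_init__(self):
        if set(self.gaps_mm) != set(SUTURE_NAMES):
            raise ValidationError(f"expected gaps for sutures {SUTURE_NAMES}")
        if any(g < 0 for g in self.gaps_mm.values()):
            raise ValidationError("suture gaps must be non-negative")
        if abs(self.sum_mm - sum(self.gaps_mm.values())) > 1e-9:
            raise ValidationError("sum_mm inconsistent with per-suture gaps")


def measure_suture_displacements(
    actual: LandmarkSet, plan: LandmarkSet, side: str
) -> SutureDisplacement:
    """Distance between each affected-side suture landmark and its plan twin."""
    suffix = "_L" if side == "left" else "_R"
    names = [f"suture_{s}{suffix}" for s in SUTURE_NAMES]
    actual.require(names)
    plan.require(names)
    gaps = {
        s: float(np.linalg.norm(actual[f"suture_{s}{suffix}"] - plan[f"suture_{s}{suffix}"]))
        for s in SUTURE_NAMES
    }
    return SutureDisplacement(gaps_mm=gaps, sum_mm=float(sum(gaps.values())))


def mirrored_plan_sutures(
    landmarks: LandmarkSet, frame: HeadFrame, affected_side: str
) -> LandmarkSet:
    """Plan suture positions: mirror of the unaffected-side suture landmarks,
    renamed to the affected side."""
    a = "_L" if affected_side == "left" else "_R"
    u = "_R" if affected_side == "left" else "_L"
    return LandmarkSet(
        {
            f"suture_{s}{a}": mirror_points(landmarks[f"suture_{s}{u}"], frame)
            for s in SUTURE_NAMES
        }
    )


# ---------------------------------------------------------------------------
# axial slice
# ---------------------------------------------------------------------------

@dataclass
class AxialZygomaSlice:
    """Axial cross-section (parallel to FH) holding both contours and the
    in-plane landmark projections, all in frame-plane coordinates (mm)."""

    plane_z_mm: float
    actual_contour: np.ndarray          # (N, 2), ordered, closed implied
    plan_contour: np.ndarray | None
    foramen_xy: np.ndarray
    arch_base_affected_xy: np.ndarray
    arch_base_unaffected_xy: np.ndarray

    def __post_init__(self):
        self.actual_contour = np.asarray(self.actual_contour, float)
        if self.actual_contour.ndim != 2 or self.actual_contour.shape[1] != 2:
            raise ValidationError("contour must be an (N, 2) point list")
        if self.plan_contour is not None:
            self.plan_contour = np.asarray(self.plan_contour, float)


def _resample_closed(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a closed polyline to roughly uniform arc spacing."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return points
    n = max(int(np.ceil(total / spacing)), 8)
    si = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(si, s, closed[:, 0])
    y = np.interp(si, s, closed[:, 1])
    return np.column_stack([x, y])


def _sample_plane(mask, affine, frame, z0, xs, ys):
    """Trilinear-sample a mask on the axial frame plane z = z0."""
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts_frame = np.column_stack(
        [X.ravel(), Y.ravel(), np.full(X.size, z0)]
    )
    world = frame.to_world(pts_frame)
    inv = np.linalg.inv(np.asarray(affine, float))
    vox = (world @ inv[:3, :3].T + inv[:3, 3]).T
    vals = ndi.map_coordinates(
        np.asarray(mask, dtype=np.float32), vox, order=1, mode="constant", cval=0.0
    )
    return vals.reshape(X.shape)


def _mask_contour_in_plane(mask, affine, frame, z0, step=CONTOUR_SPACING_MM):
    mask = np.asarray(mask)
    if not mask.any():
        raise SliceError("mask is empty")
    idx = np.argwhere(mask)
    corners_vox = np.array(
        [[i, j, k] for i in (idx[:, 0].min(), idx[:, 0].max())
         for j in (idx[:, 1].min(), idx[:, 1].max())
         for k in (idx[:, 2].min(), idx[:, 2].max())], dtype=float
    )
    A = np.asarray(affine, float)
    corners_world = corners_vox @ A[:3, :3].T + A[:3, 3]
    corners_frame = frame.to_frame(corners_world)
    if z0 < corners_frame[:, 2].min() - 2 or z0 > corners_frame[:, 2].max() + 2:
        raise SliceError("plane lies outside the mask extent")
    margin = 4.0
    xs = np.arange(corners_frame[:, 0].min() - margin,
                   corners_frame[:, 0].max() + margin, step)
    ys = np.arange(corners_frame[:, 1].min() - margin,
                   corners_frame[:, 1].max() + margin, step)
    field = _sample_plane(mask, affine, frame, z0, xs, ys)
    contours = measure.find_contours(field, 0.5)
    if not contours:
        raise SliceError("plane does not intersect the mask")
    # longest contour by perimeter
    def perim(c):
        return float(np.linalg.norm(np.diff(c, axis=0), axis=1).sum())
    c = max(contours, key=perim)
    pts = np.column_stack([xs[0] + c[:, 0] * step, ys[0] + c[:, 1] * step])
    return _resample_closed(pts, CONTOUR_SPACING_MM)


def default_prominence(mask, affine, frame) -> np.ndarray:
    """Centroid of the mask's widest axial (frame-z) cross-section, in world
    coordinates — the fallback when no prominence landmark is supplied."""
    mask = np.asarray(mask)
    if not mask.any():
        raise SliceError("mask is empty")
    A = np.asarray(affine, float)
    idx = np.argwhere(mask).astype(float)
    world = idx @ A[:3, :3].T + A[:3, 3]
    zf = frame.to_frame(world)[:, 2]
    bins = np.round(zf).astype(int)
    vals, counts = np.unique(bins, return_counts=True)
    best = vals[np.argmax(counts)]
    return world[bins == best].mean(axis=0)


def select_axial_slice(
    zygoma_mask,
    affine,
    frame: HeadFrame,
    prominence_landmark,
    landmarks: LandmarkSet,
    affected_side: str,
    plan_mask=None,
    plan_affine=None,
) -> AxialZygomaSlice:
    """Build the measurement slice through the prominence, parallel to FH."""
    z0 = float(frame.to_frame(np.asarray(prominence_landmark, float))[2])
    actual = _mask_contour_in_plane(zygoma_mask, affine, frame, z0)
    plan = None
    if plan_mask is not None:
        plan = _mask_contour_in_plane(
            plan_mask, plan_affine if plan_affine is not None else affine, frame, z0
        )
    a = "_L" if affected_side == "left" else "_R"
    u = "_R" if affected_side == "left" else "_L"
    landmarks.require([f"infraorbital_foramen{a}", f"arch_base{a}", f"arch_base{u}"])
    proj = lambda p: frame.to_frame(p)[:2]
    return AxialZygomaSlice(
        plane_z_mm=z0,
        actual_contour=actual,
        plan_contour=plan,
        foramen_xy=proj(landmarks[f"infraorbital_foramen{a}"]),
        arch_base_affected_xy=proj(landmarks[f"arch_base{a}"]),
        arch_base_unaffected_xy=proj(landmarks[f"arch_base{u}"]),
    )


# ---------------------------------------------------------------------------
# point constructions
# ---------------------------------------------------------------------------

def compute_O(slice_: AxialZygomaSlice) -> np.ndarray:
    """Intersection of the arch-base line with the vertical midline (x = 0)."""
    a = np.asarray(slice_.arch_base_affected_xy, float)
    b = np.asarray(slice_.arch_base_unaffected_xy, float)
    d = b - a
    if abs(d[0]) < 1e-9:
        raise DegenerateSpanError(
            "arch-base line is parallel to (or lies on) the midline"
        )
    t = (0.0 - a[0]) / d[0]
    return np.array([0.0, a[1] + t * d[1]])


def _cross2(a, b):
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _ray_contour_hits(origin, direction, contour):
    """Intersections of the ray origin + t*direction (t > 0) with a closed
    contour; returns sorted hit parameters t and points."""
    P = np.vstack([contour, contour[:1]])
    A, B = P[:-1], P[1:]
    e = B - A
    d = np.asarray(direction, float)
    denom = _cross2(np.broadcast_to(d, e.shape), e)
    diff = A - np.asarray(origin, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = _cross2(diff, e) / denom
        u = _cross2(diff, np.broadcast_to(d, e.shape)) / denom
    ok = (np.abs(denom) > 1e-12) & (t > 1e-9) & (u >= -1e-9) & (u <= 1 + 1e-9)
    t = t[ok]
    order = np.argsort(t)
    t = t[order]
    pts = np.asarray(origin, float) + t[:, None] * d
    return t, pts


def construct_zygoma_points(slice_: AxialZygomaSlice, O: np.ndarray) -> np.ndarray:
    """Z1..Z5: ray/contour intersections at interior angle fractions k/6 of
    the span between the infraorbital foramen and the affected arch base,
    taking the outermost intersection (the facial surface of the zygoma)."""
    O = np.asarray(O, float)
    va = np.asarray(slice_.foramen_xy, float) - O
    vb = np.asarray(slice_.arch_base_affected_xy, float) - O
    if np.linalg.norm(va) < 1e-9 or np.linalg.norm(vb) < 1e-9:
        raise DegenerateSpanError("a bounding landmark coincides with O")
    theta_a = np.arctan2(va[1], va[0])
    theta_b = np.arctan2(vb[1], vb[0])
    span = (theta_b - theta_a + np.pi) % (2 * np.pi) - np.pi
    if abs(span) < 1e-9:
        raise DegenerateSpanError("zero angular span between foramen and arch base")
    Z = np.empty((5, 2))
    for k in range(1, 6):
        theta = theta_a + span * k / 6.0
        d = np.array([np.cos(theta), np.sin(theta)])
        t, pts = _ray_contour_hits(O, d, slice_.actual_contour)
        if t.size == 0:
            raise RayMissError(
                f"ray at {np.degrees(theta):.2f} deg misses the actual contour",
                angle_deg=float(np.degrees(theta)),
            )
        Z[k - 1] = pts[-1]  # outermost
    return Z


def compute_plan_points(
    slice_: AxialZygomaSlice, O: np.ndarray, Z: np.ndarray
) -> np.ndarray:
    """P1..P5: intersection of each line O–Zk with the plan contour (the hit
    nearest Zk when there are several)."""
    if slice_.plan_contour is None:
        raise ValidationError("slice carries no plan contour")
    O = np.asarray(O, float)
    P = np.empty((5, 2))
    for k in range(5):
        d = Z[k] - O
        nd = np.linalg.norm(d)
        if nd < 1e-9:
            raise DegenerateSpanError(f"Z{k + 1} coincides with O")
        d = d / nd
        _, pts = _ray_contour_hits(O, d, slice_.plan_contour)
        if pts.shape[0] == 0:
            raise RayMissError(
                f"line O-Z{k + 1} misses the plan contour",
                angle_deg=float(np.degrees(np.arctan2(d[1], d[0]))),
            )
        P[k] = pts[np.argmin(np.linalg.norm(pts - Z[k], axis=1))]
    return P


def deviation_index(distances) -> float:
    """DI = sum of the five Zi–Pi distances (mm)."""
    d = np.asarray(distances, dtype=float)
    if d.shape != (5,):
        raise ValidationError("deviation index needs exactly five distances")
    if np.any(d < 0):
        raise ValidationError("distances must be non-negative")
    return float(d.sum())


def radial_sums(Z, P, O) -> tuple[float, float]:
    """(Σ|ZiO|, Σ|PiO|) — conformance sums between result and plan."""
    Z, P, O = np.asarray(Z, float), np.asarray(P, float), np.asarray(O, float)
    return (
        float(np.linalg.norm(Z - O, axis=1).sum()),
        float(np.linalg.norm(P - O, axis=1).sum()),
    )


@dataclass(frozen=True)
class DeviationIndexResult:
    O: np.ndarray
    Z: np.ndarray                # (5, 2) points on the actual contour
    P: np.ndarray                # (5, 2) points on the plan contour
    distances_mm: np.ndarray     # (5,)
    DI: float
    ZO_sum_mm: float
    PO_sum_mm: float

    def __post_init__(self):
        if abs(self.DI - float(np.sum(self.distances_mm))) > 1e-9:
            raise ValidationError("DI must equal the sum of the five distances")
        if np.any(np.asarray(self.distances_mm) < 0):
            raise ValidationError("distances must be non-negative")


def deviation_index_result(slice_: AxialZygomaSlice) -> DeviationIndexResult:
    """Full Fig.-style construction on a prepared slice."""
    O = compute_O(slice_)
    Z = construct_zygoma_points(slice_, O)
    P = compute_plan_points(slice_, O, Z)
    d = np.linalg.norm(Z - P, axis=1)
    zo, po = radial_sums(Z, P, O)
    return DeviationIndexResult(
        O=O, Z=Z, P=P, distances_mm=d, DI=float(d.sum()),
        ZO_sum_mm=zo, PO_sum_mm=po,
    )
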