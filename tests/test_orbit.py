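"""Orbital volume, floor thirds and transition-zone angle estimation."""
import warnings

import numpy as np
import pytest
import scipy.ndimage as ndi

from zmo import (
    PhantomSpec,
    bilateral_orbit_metrics,
    build_phantom,
    compute_head_frame,
    floor_thirds,
    label_mask,
    orbital_volume,
    transition_zone_angle,
)
from zmo.exceptions import SliceError, ValidationError

from conftest import wedge_mask


def half_ellipsoid_mask(a, b, c, spacing):
    """Half-ellipsoid (open anteriorly at the rim plane y <= 0)."""
    nx = int(2 * (a + 2) / spacing)
    ny = int((b + 4) / spacing)
    nz = int(2 * (c + 2) / spacing)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    # quarter-voxel offset: generic grid alignment, no voxel centre exactly
    # on the rim plane or symmetry planes
    affine[:3, 3] = np.array([-(a + 2), -(b + 2), -(c + 2)]) + spacing / 4.0
    xs = affine[0, 3] + spacing * np.arange(nx)
    ys = affine[1, 3] + spacing * np.arange(ny)
    zs = affine[2, 3] + spacing * np.arange(nz)
    X, Y, Z = xs[:, None, None], ys[None, :, None], zs[None, None, :]
    m = ((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0) & (Y <= 0.0)
    return np.broadcast_to(m, (nx, ny, nz)).copy(), affine


class TestOrbitalVolume:
    def test_empty_mask_is_zero(self):
        assert orbital_volume(np.zeros((5, 5, 5), bool), np.eye(4)) == 0.0

    def test_voxel_block_definition(self):
        m = np.zeros((20, 20, 20), bool)
        m[5:15, 5:15, 5:15] = True
        assert orbital_volume(m, np.eye(4)) == 1000.0
        assert orbital_volume(m, np.eye(4), unit="cm3") == 1.0

    def test_half_ellipsoid_matches_analytic_volume(self):
        a, b, c = 20.0, 15.0, 17.5
        m, aff = half_ellipsoid_mask(a, b, c, 0.5)
        analytic = 2.0 / 3.0 * np.pi * a * b * c
        assert orbital_volume(m, aff) == pytest.approx(analytic, rel=0.02)

    def test_clipping_at_symmetry_plane_halves_volume(self):
        a, b, c = 20.0, 15.0, 17.5
        m, aff = half_ellipsoid_mask(a, b, c, 0.5)
        xs = aff[0, 3] + 0.5 * np.arange(m.shape[0])
        clipped = m & (xs[:, None, None] <= 0.0)
        v, vc = orbital_volume(m, aff), orbital_volume(clipped, aff)
        assert vc == pytest.approx(v / 2.0, rel=0.02)

    def test_rotation_invariance_within_two_percent(self):
        m, aff = half_ellipsoid_mask(20.0, 15.0, 17.5, 0.5)
        v0 = orbital_volume(m, aff)
        rot = ndi.rotate(m.astype(np.uint8), 17.0, axes=(0, 1), order=0, reshape=True)
        assert orbital_volume(rot.astype(bool), aff) == pytest.approx(v0, rel=0.02)

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValidationError):
            orbital_volume(np.full((4, 4, 4), 2, dtype=int), np.eye(4))

    def test_closing_fills_interior_pits(self):
        m = np.zeros((30, 30, 30), bool)
        m[5:25, 5:25, 5:25] = True
        m[14:16, 14:16, 14:16] = False  # interior defect
        v_open = orbital_volume(m, np.eye(4))
        v_closed = orbital_volume(m, np.eye(4), closing_radius_mm=2.0)
        assert v_closed > v_open


class TestFloorThirds:
    def test_straight_floor_thirds_positions(self, identity_frame):
        # box cavity: flat floor of length 30 mm along the anterior axis
        m = np.zeros((40, 40, 25), bool)
        m[5:35, 5:35, 5:20] = True
        aff = np.eye(4)
        aff[:3, 3] = (-20.0, -20.0, -10.0)
        t = floor_thirds(m, aff, identity_frame)
        L = t.floor_length_mm
        assert L == pytest.approx(30.0, abs=1.5)
        assert t.arc_positions_mm == pytest.approx(
            (L / 6, L / 2, 5 * L / 6), abs=1e-9
        )
        # anterior third plane is anterior of the posterior one
        assert t.frame_y_mm[0] > t.frame_y_mm[2]

    def test_quarter_circle_floor_arc_length(self, identity_frame):
        r = 24.0
        spacing = 0.5
        n = int(2 * r / spacing) + 20
        aff = np.diag([spacing] * 3 + [1.0])
        aff[:3, 3] = (-10.0, -5.0, -r - 3)
        xs = aff[0, 3] + spacing * np.arange(n)
        ys = aff[1, 3] + spacing * np.arange(n)
        zs = aff[2, 3] + spacing * np.arange(n)
        X, Y, Z = xs[:, None, None], ys[None, :, None], zs[None, None, :]
        floor = -np.sqrt(np.maximum(r**2 - np.minimum(Y, r) ** 2, 0.0))
        m = (Y >= 0) & (Y <= r) & (Z >= floor) & (Z <= 5.0) & (np.abs(X) <= 8.0)
        m = np.broadcast_to(m, (n, n, n)).copy()
        t = floor_thirds(m, aff, identity_frame)
        assert t.floor_length_mm == pytest.approx(np.pi * r / 2.0, rel=0.05)

    def test_mirror_symmetric_orbits_get_identical_thirds(self, symmetric_phantom):
        img, lm, _ = symmetric_phantom
        frame = compute_head_frame(lm)
        mL, aff = label_mask(img, "orbit_L")
        mR, _ = label_mask(img, "orbit_R")
        tL, tR = floor_thirds(mL, aff, frame), floor_thirds(mR, aff, frame)
        assert tL.frame_y_mm == pytest.approx(tR.frame_y_mm, abs=1.0)

    def test_too_short_floor_raises(self, identity_frame):
        m = np.zeros((10, 10, 10), bool)
        m[5, 5, 5] = True
        with pytest.raises(SliceError):
            floor_thirds(m, np.eye(4), identity_frame)


class TestTransitionZoneAngle:
    @pytest.mark.parametrize("alpha", [90.0, 135.0])
    @pytest.mark.parametrize("side", ["right", "left"])
    def test_wedge_angle_recovered_within_two_degrees(self, alpha, side,
                                                      identity_frame):
        m, aff = wedge_mask(alpha, spacing=0.5, side=side)
        y = identity_frame.to_frame(np.array([0.0, 10.0, 0.0]))[1]
        ang = transition_zone_angle(m, aff, identity_frame, y, side)
        assert ang == pytest.approx(alpha, abs=2.0)

    def test_flat_boundary_returns_180_with_warning(self, identity_frame):
        m, aff = wedge_mask(0.0, spacing=0.5, flat=True)
        y = identity_frame.to_frame(np.array([0.0, 10.0, 0.0]))[1]
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            ang = transition_zone_angle(m, aff, identity_frame, y, "right")
        assert ang == 180.0
        assert any("180" in str(w.message) for w in rec)

    def test_scale_invariance_within_one_degree(self, identity_frame):
        m1, a1 = wedge_mask(135.0, spacing=0.5, size_scale=1.0)
        m2, a2 = wedge_mask(135.0, spacing=0.5, size_scale=2.0)
        y = identity_frame.to_frame(np.array([0.0, 10.0, 0.0]))[1]
        ang1 = transition_zone_angle(m1, a1, identity_frame, y, "right")
        ang2 = transition_zone_angle(m2, a2, identity_frame, y, "right")
        assert ang1 == pytest.approx(ang2, abs=1.0)


class TestBilateralMetrics:
    def test_symmetric_phantom_has_null_differences(self, symmetric_phantom):
        img, lm, _ = symmetric_phantom
        frame = compute_head_frame(lm)
        mL, aff = label_mask(img, "orbit_L")
        mR, _ = label_mask(img, "orbit_R")
        om = bilateral_orbit_metrics(mL, mR, aff, frame, "left")
        assert om.volume_diff <= 0.01 * om.volume_unaffected
        assert max(om.angle_diff_deg) < 2.0

    def test_volume_and_angle_diffs_symmetric_in_argument_order(
        self, symmetric_phantom
    ):
        img, lm, _ = symmetric_phantom
        frame = compute_head_frame(lm)
        mL, aff = label_mask(img, "orbit_L")
        mR, _ = label_mask(img, "orbit_R")
        ab = bilateral_orbit_metrics(mL, mR, aff, frame, "left")
        ba = bilateral_orbit_metrics(mR, mL, aff, frame, "right")
        assert ab.volume_diff == pytest.approx(ba.volume_diff, abs=1e-9)
        assert ab.angle_diff_deg == pytest.approx(ba.angle_diff_deg, abs=1e-9)

    def test_opened_middle_third_detected_in_middle_band_only(self):
        img, lm, _ = build_phantom(
            PhantomSpec(
                voxel_spacing_mm=(0.5, 0.5, 0.5),
                affected_buttress_angles_deg=(135.0, 165.0, 135.0),
            )
        )
        frame = compute_head_frame(lm)
        mL, aff = label_mask(img, "orbit_L")
        mR, _ = label_mask(img, "orbit_R")
        om = bilateral_orbit_metrics(mL, mR, aff, frame, "left")
        assert om.angle_diff_deg[1] == pytest.approx(30.0, abs=3.0)
        assert om.angle_diff_deg[0] < 3.0
        assert om.angle_diff_deg[2] < 3.0

    def test_known_increment_recovered(self):
        img, lm, truth = build_phantom(
            PhantomSpec(
                voxel_spacing_mm=(0.5, 0.5, 0.5),
                orbital_volume_increment_mm3=3930.0,
            )
        )
        frame = compute_head_frame(lm)
        mL, aff = label_mask(img, "orbit_L")
        mR, _ = label_mask(img, "orbit_R")
        om = bilateral_orbit_metrics(mL, mR, aff, frame, "left", unit="cm3")
        assert om.volume_diff == pytest.approx(3.93, rel=0.02)
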