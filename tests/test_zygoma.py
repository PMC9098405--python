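"""Suture displacement and deviation-index constructions."""
import numpy as np
import pytest

from zmo import (
    AxialZygomaSlice,
    LandmarkSet,
    RigidTransform,
    build_phantom,
    compute_head_frame,
    compute_O,
    compute_plan_points,
    construct_zygoma_points,
    deviation_index,
    deviation_index_result,
    label_mask,
    measure_suture_displacements,
    mirror_mask,
    mirrored_plan_sutures,
    PhantomSpec,
    radial_sums,
    select_axial_slice,
)
from zmo.exceptions import (
    DegenerateSpanError,
    RayMissError,
    SliceError,
    ValidationError,
)
from zmo.zygoma import CONTOUR_SPACING_MM

from conftest import arc_contour


def make_slice(actual, plan=None, foramen=(0.0, 40.0), arch_a=(40.0, 0.0),
               arch_u=(-40.0, 0.0)):
    return AxialZygomaSlice(
        plane_z_mm=0.0,
        actual_contour=actual,
        plan_contour=plan,
        foramen_xy=np.asarray(foramen, float),
        arch_base_affected_xy=np.asarray(arch_a, float),
        arch_base_unaffected_xy=np.asarray(arch_u, float),
    )


class TestSutureDisplacement:
    def test_identical_sets_give_zero(self):
        lm = LandmarkSet(
            {f"suture_{s}_L": (float(i), 2.0, 3.0)
             for i, s in enumerate(("ZM", "ZF", "IO", "ZS", "ZT"))}
        )
        d = measure_suture_displacements(lm, lm, "left")
        assert d.sum_mm == 0.0

    def test_rigid_translation_gives_uniform_gaps(self):
        pts = {f"suture_{s}_L": (float(i), 2.0, 3.0)
               for i, s in enumerate(("ZM", "ZF", "IO", "ZS", "ZT"))}
        lm = LandmarkSet(pts)
        shifted = LandmarkSet({k: np.asarray(v) + [3.0, 0, 0] for k, v in pts.items()})
        d = measure_suture_displacements(shifted, lm, "left")
        assert all(g == pytest.approx(3.0, abs=1e-12) for g in d.gaps_mm.values())
        assert d.sum_mm == pytest.approx(15.0, abs=1e-12)

    def test_phantom_gaps_match_truth(self):
        spec = PhantomSpec(zygoma_rotation_deg=3.0, zygoma_translation_mm=(-1, 2, 0))
        _, lm, truth = build_phantom(spec)
        frame = compute_head_frame(lm)
        plan = mirrored_plan_sutures(lm, frame, "left")
        d = measure_suture_displacements(lm, plan, "left")
        for s, g in d.gaps_mm.items():
            assert g == pytest.approx(truth.true_suture_gaps_mm[s], abs=1e-6)

    def test_missing_suture_is_named(self):
        lm = LandmarkSet({"suture_ZM_L": (0, 0, 0)})
        with pytest.raises(ValidationError, match="suture_ZF_L"):
            measure_suture_displacements(lm, lm, "left")


class TestComputeO:
    def test_symmetric_arch_bases(self):
        s = make_slice(arc_contour((0, 0), 30, 0, 90),
                       arch_a=(40.0, -30.0), arch_u=(-40.0, -30.0))
        assert np.allclose(compute_O(s), [0.0, -30.0], atol=1e-12)

    def test_tilted_arch_base_line(self):
        s = make_slice(arc_contour((0, 0), 30, 0, 90),
                       arch_a=(40.0, -28.0), arch_u=(-40.0, -30.0))
        assert np.allclose(compute_O(s), [0.0, -29.0], atol=1e-12)

    def test_arch_bases_on_midline_degenerate(self):
        s = make_slice(arc_contour((0, 0), 30, 0, 90),
                       arch_a=(0.0, -30.0), arch_u=(0.0, 10.0))
        with pytest.raises(DegenerateSpanError):
            compute_O(s)


class TestZygomaPoints:
    def test_circular_arc_gives_points_at_closed_form_angles(self):
        O = np.array([0.0, 0.0])
        r = 40.0
        s = make_slice(arc_contour(O, r, -5, 95), foramen=(0.0, 10.0),
                       arch_a=(10.0, 0.0))
        Z = construct_zygoma_points(s, O)
        # rays at 75, 60, 45, 30, 15 degrees from +x (span from foramen at 90)
        expected = np.array(
            [[r * np.cos(np.radians(a)), r * np.sin(np.radians(a))]
             for a in (75, 60, 45, 30, 15)]
        )
        assert np.allclose(Z, expected, atol=2 * CONTOUR_SPACING_MM)
        assert np.allclose(np.linalg.norm(Z - O, axis=1), r, atol=0.05)

    def test_zero_span_raises(self):
        s = make_slice(arc_contour((0, 0), 30, 0, 90), foramen=(10.0, 0.0),
                       arch_a=(20.0, 0.0))
        with pytest.raises(DegenerateSpanError):
            construct_zygoma_points(s, np.array([0.0, 0.0]))

    def test_ray_missing_contour_reports_angle(self):
        # tiny arc far from the ray span
        s = make_slice(arc_contour((0, 0), 30, 80, 90), foramen=(10.0, 0.0),
                       arch_a=(0.0, 10.0))
        with pytest.raises(RayMissError) as exc:
            construct_zygoma_points(s, np.array([0.0, 0.0]))
        assert exc.value.angle_deg is not None


class TestPlanPoints:
    def test_identical_contours_give_zero_distances(self):
        O = np.array([0.0, 0.0])
        arc = arc_contour(O, 40, -5, 95)
        s = make_slice(arc, plan=arc.copy(), foramen=(0.0, 10.0), arch_a=(10.0, 0.0))
        Z = construct_zygoma_points(s, O)
        P = compute_plan_points(s, O, Z)
        assert np.allclose(np.linalg.norm(Z - P, axis=1), 0.0, atol=1e-9)

    @pytest.mark.parametrize("delta", [1.0, 2.0, 3.0])
    def test_concentric_circles_give_exact_radial_offset(self, delta):
        O = np.array([0.0, 0.0])
        s = make_slice(
            arc_contour(O, 40, -5, 95),
            plan=arc_contour(O, 40 + delta, -5, 95),
            foramen=(0.0, 10.0),
            arch_a=(10.0, 0.0),
        )
        Z = construct_zygoma_points(s, O)
        P = compute_plan_points(s, O, Z)
        d = np.linalg.norm(Z - P, axis=1)
        assert np.allclose(d, delta, atol=0.05)
        assert deviation_index(d) == pytest.approx(5 * delta, abs=0.1)

    def test_radial_sums_match_geometry(self):
        O = np.array([0.0, 0.0])
        s = make_slice(
            arc_contour(O, 40, -5, 95), plan=arc_contour(O, 42, -5, 95),
            foramen=(0.0, 10.0), arch_a=(10.0, 0.0),
        )
        Z = construct_zygoma_points(s, O)
        P = compute_plan_points(s, O, Z)
        zo, po = radial_sums(Z, P, O)
        assert zo == pytest.approx(5 * 40, abs=0.3)
        assert po == pytest.approx(5 * 42, abs=0.3)


class TestDeviationIndex:
    def test_aggregates_five_distances(self):
        assert deviation_index([1, 1, 1, 1, 1]) == 5.0
        assert deviation_index([0, 0, 0, 0, 0]) == 0.0

    def test_wrong_arity_or_negative_rejected(self):
        with pytest.raises(ValidationError):
            deviation_index([1, 2, 3])
        with pytest.raises(ValidationError):
            deviation_index([1, 2, 3, -1, 5])

    def test_monotone_in_radial_offset(self):
        O = np.array([0.0, 0.0])
        dis = []
        for delta in (0.5, 1.0, 2.0, 4.0):
            s = make_slice(
                arc_contour(O, 40, -5, 95), plan=arc_contour(O, 40 + delta, -5, 95),
                foramen=(0.0, 10.0), arch_a=(10.0, 0.0),
            )
            Z = construct_zygoma_points(s, O)
            dis.append(deviation_index(
                np.linalg.norm(Z - compute_plan_points(s, O, Z), axis=1)
            ))
        assert all(b > a for a, b in zip(dis, dis[1:]))


class TestMaskSlice:
    def test_symmetric_phantom_contours_coincide(self, symmetric_phantom):
        img, lm, _ = symmetric_phantom
        frame = compute_head_frame(lm)
        actual, aff = label_mask(img, "zygoma_L")
        unaff, _ = label_mask(img, "zygoma_R")
        plan = mirror_mask(unaff, aff, frame)
        sl = select_axial_slice(
            actual, aff, frame, lm["zygoma_prominence_L"], lm, "left",
            plan_mask=plan,
        )
        res = deviation_index_result(sl)
        assert res.DI <= 5 * 0.5  # half a voxel per ray at 1 mm spacing
        assert res.ZO_sum_mm == pytest.approx(res.PO_sum_mm, abs=5 * 0.5)

    def test_contour_radius_matches_shell_construction(self, symmetric_phantom):
        img, lm, _ = symmetric_phantom
        frame = compute_head_frame(lm)
        actual, aff = label_mask(img, "zygoma_L")
        sl = select_axial_slice(
            actual, aff, frame, lm["zygoma_prominence_L"], lm, "left"
        )
        res_O = compute_O(sl)
        Z = construct_zygoma_points(sl, res_O)
        # outer shell surface radius is 59 mm about the arch-base line centre
        assert np.allclose(np.linalg.norm(Z - res_O, axis=1), 59.0, atol=1.0)

    def test_plane_outside_mask_raises(self, symmetric_phantom):
        img, lm, _ = symmetric_phantom
        frame = compute_head_frame(lm)
        actual, aff = label_mask(img, "zygoma_L")
        far = lm["zygoma_prominence_L"] + np.array([0.0, 0.0, 200.0])
        with pytest.raises(SliceError):
            select_axial_slice(actual, aff, frame, far, lm, "left")


class TestRigidInvariance:
    def test_suture_and_di_invariant_under_joint_world_transform(self):
        rng = np.random.default_rng(11)
        _, lm, _ = build_phantom(PhantomSpec(zygoma_translation_mm=(-2.5, 1.0, 0.0)))
        frame = compute_head_frame(lm)
        plan = mirrored_plan_sutures(lm, frame, "left")
        d0 = measure_suture_displacements(lm, plan, "left")

        # analytic world-space contours for the DI path
        th = np.radians(np.linspace(100, 185, 400))
        centre = np.array([0.0, -55.0, 0.0])
        actual3d = centre + 59.0 * np.column_stack(
            [np.cos(th), np.sin(th), np.zeros_like(th)]
        )
        plan3d = centre + 56.5 * np.column_stack(
            [np.cos(th), np.sin(th), np.zeros_like(th)]
        )

        def di_for(lms, pts_a, pts_p):
            fr = compute_head_frame(lms)
            to2d = lambda P: fr.to_frame(P)[:, :2]
            sl = AxialZygomaSlice(
                plane_z_mm=0.0,
                actual_contour=to2d(pts_a),
                plan_contour=to2d(pts_p),
                foramen_xy=fr.to_frame(lms["infraorbital_foramen_L"])[:2],
                arch_base_affected_xy=fr.to_frame(lms["arch_base_L"])[:2],
                arch_base_unaffected_xy=fr.to_frame(lms["arch_base_R"])[:2],
            )
            return deviation_index_result(sl)

        base = di_for(lm, actual3d, plan3d)
        for _ in range(3):
            axis = rng.normal(size=3)
            T = RigidTransform.from_axis_angle(
                axis, rng.uniform(-25, 25), translation=rng.uniform(-30, 30, 3)
            )
            lm_t = lm.transform(T)
            plan_t = mirrored_plan_sutures(lm_t, compute_head_frame(lm_t), "left")
            d_t = measure_suture_displacements(lm_t, plan_t, "left")
            for s in d0.gaps_mm:
                assert d_t.gaps_mm[s] == pytest.approx(d0.gaps_mm[s], abs=1e-6)
            moved = di_for(lm_t, T.apply(actual3d), T.apply(plan3d))
            assert moved.DI == pytest.approx(base.DI, abs=1e-6)
            assert np.allclose(moved.distances_mm, base.distances_mm, atol=1e-6)
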