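"""Muscle path geometry, tendon-excursion moment arms and architectural
parameter estimation."""

import numpy as np
import pytest

from bipedsim.model import Pose, forward_kinematics, transform_point
from bipedsim.muscles import (ArchitectureRow, MusclePath, MUSCLE_GROUPS,
                              attachment_centroid, fmax_from_mass,
                              moment_arm, mtu_length, scale_architecture)


def _straight_muscle(p0, p1):
    return MusclePath("toy", [("base", np.asarray(p0)),
                              ("foot", np.asarray(p1))])


class TestMtuLength:
    def test_same_segment_points_pose_independent(self, hinge_model_factory):
        model = hinge_model_factory()
        muscle = MusclePath("m", [("base", (0, 0, 0)), ("base", (0.1, 0, 0)),
                                  ("foot", (0, 0, 0))])
        for q in (0.0, 30.0, -45.0):
            # the base-to-base section stays 0.1 m under any pose
            length = mtu_length(model, Pose({"q": q}), muscle)
            assert length >= 0.1 - 1e-12

    def test_collinear_via_point_adds_nothing(self, hinge_model_factory):
        model = hinge_model_factory()
        direct = _straight_muscle((-0.1, 0.02, 0), (0.1, 0.02, 0))
        with_via = MusclePath("m", [("base", (-0.1, 0.02, 0)),
                                    ("base", (0.0, 0.02, 0)),
                                    ("foot", (0.1, 0.02, 0))])
        pose = Pose({"q": 0.0})
        assert mtu_length(model, pose, with_via) == pytest.approx(
            mtu_length(model, pose, direct), abs=1e-15)

    def test_random_path_against_transform_oracle(self, hinge_model_factory):
        rng = np.random.default_rng(5)
        axis = rng.normal(size=3)
        model = hinge_model_factory(axis=axis / np.linalg.norm(axis))
        pts = [("base", rng.normal(size=3) * 0.1),
               ("foot", rng.normal(size=3) * 0.1),
               ("foot", rng.normal(size=3) * 0.1)]
        muscle = MusclePath("m", pts)
        pose = Pose({"q": 37.5})
        transforms = forward_kinematics(model, pose)
        world = [transform_point(transforms[s], p) for s, p in pts]
        expected = sum(np.linalg.norm(b - a) for a, b in zip(world, world[1:]))
        assert mtu_length(model, pose, muscle) == pytest.approx(expected,
                                                                abs=1e-12)

    def test_unresolvable_segment_raises(self, hinge_model_factory):
        model = hinge_model_factory()
        muscle = MusclePath("m", [("base", (0, 0, 0)), ("wing", (1, 0, 0))])
        with pytest.raises(KeyError, match="wing"):
            mtu_length(model, Pose({"q": 0.0}), muscle)


class TestMomentArm:
    def test_perpendicular_distance_closed_form(self, hinge_model_factory):
        model = hinge_model_factory(axis=(0, 0, 1))
        muscle = _straight_muscle((-0.05, 0.02, 0), (0.05, 0.02, 0))
        r = moment_arm(model, Pose({"q": 0.0}), muscle, "q")
        assert abs(r) == pytest.approx(0.02, abs=1e-6)

    def test_path_through_joint_centre_is_zero(self, hinge_model_factory):
        model = hinge_model_factory(axis=(0, 0, 1))
        muscle = _straight_muscle((-0.05, 0.0, 0), (0.05, 0.0, 0))
        assert moment_arm(model, Pose({"q": 0.0}), muscle, "q") == \
            pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_hinge_against_analytic_oracle(self, seed,
                                                  hinge_model_factory):
        rng = np.random.default_rng(seed)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        model = hinge_model_factory(axis=axis)
        p0 = rng.normal(size=3) * 0.1
        p1 = rng.normal(size=3) * 0.1
        muscle = _straight_muscle(p0, p1)
        r = moment_arm(model, Pose({"q": 0.0}), muscle, "q")
        # dL/dq = u . (axis x p1) for the moving endpoint, so
        # r = -u . (axis x p1)
        u = (p1 - p0) / np.linalg.norm(p1 - p0)
        assert r == pytest.approx(-float(u @ np.cross(axis, p1)), abs=1e-6)

    def test_translation_dof_rejected(self, full_bundle):
        model = full_bundle.model
        muscle = full_bundle.muscles()[0]
        with pytest.raises(ValueError, match="translation"):
            moment_arm(model, model.default_pose(), muscle, "pelvis_tx")

    def test_mirror_antisymmetry(self, hinge_model_factory):
        # mirroring the path across the x-z plane (which contains the
        # hinge axis z) negates the moment arm
        model = hinge_model_factory(axis=(0, 0, 1))
        p0, p1 = np.array([-0.06, 0.03, 0.01]), np.array([0.07, 0.015, -0.02])
        r = moment_arm(model, Pose({"q": 10.0}), _straight_muscle(p0, p1), "q")
        m = np.array([1, -1, 1])
        r_m = moment_arm(model, Pose({"q": -10.0}),
                         _straight_muscle(p0 * m, p1 * m), "q")
        assert r_m == pytest.approx(-r, abs=1e-9)

    def test_tendon_excursion_integral_consistency(self, hinge_model_factory):
        model = hinge_model_factory(axis=(0, 0, 1))
        muscle = _straight_muscle((-0.08, 0.025, 0.01), (0.06, -0.01, 0.0))
        qs = np.linspace(-30.0, 45.0, 151)
        arms = np.array([moment_arm(model, Pose({"q": q}), muscle, "q")
                         for q in qs])
        integral = np.trapezoid(arms, np.deg2rad(qs))
        delta_l = (mtu_length(model, Pose({"q": qs[-1]}), muscle)
                   - mtu_length(model, Pose({"q": qs[0]}), muscle))
        assert integral == pytest.approx(-delta_l, abs=1e-4)


class TestAttachmentCentroid:
    def test_single_vertex_any_method(self):
        v = np.array([[0.1, 0.2, 0.3]])
        for method in ("model1_alpha", "model2_hull", "model3_arithmetic"):
            assert attachment_centroid(v, method) == pytest.approx(v[0])

    def test_square_corners_methods_agree_on_centre(self):
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
                          dtype=float)
        for method in ("model2_hull", "model3_arithmetic"):
            assert attachment_centroid(square, method) == pytest.approx(
                [0.5, 0.5, 0.0], abs=1e-12)

    def test_hull_centroid_against_fan_triangulation_oracle(self):
        rng = np.random.default_rng(9)
        pts2 = rng.uniform(-1, 1, size=(25, 2))
        # embed in a tilted 3-D plane
        from scipy.spatial import ConvexHull
        from bipedsim.model import rotation_matrix
        R = rotation_matrix(np.array([1.0, 2.0, 0.5])
                            / np.linalg.norm([1.0, 2.0, 0.5]), 0.7)
        origin = np.array([0.3, -0.2, 0.9])
        pts3 = origin + np.column_stack([pts2, np.zeros(25)]) @ R.T
        got = attachment_centroid(pts3, "model2_hull")
        hull = ConvexHull(pts2)
        poly = pts2[hull.vertices]
        # fan triangulation area centroid
        areas, centroids = [], []
        for i in range(1, len(poly) - 1):
            a, b, c = poly[0], poly[i], poly[i + 1]
            areas.append(0.5 * abs((b - a)[0] * (c - a)[1]
                                   - (b - a)[1] * (c - a)[0]))
            centroids.append((a + b + c) / 3.0)
        c2 = np.average(centroids, axis=0, weights=areas)
        expected = origin + np.append(c2, 0.0) @ R.T
        assert np.abs(got - expected).max() < 1e-9

    def test_alpha_shape_recovers_hull_for_dense_convex_patch(self):
        rng = np.random.default_rng(2)
        pts2 = rng.uniform(0, 0.01, size=(200, 2))
        pts3 = np.column_stack([pts2, np.zeros(200)])
        alpha = attachment_centroid(pts3, "model1_alpha")
        hull = attachment_centroid(pts3, "model2_hull")
        assert np.abs(alpha - hull).max() < 5e-4

    def test_empty_patch_raises(self):
        with pytest.raises(ValueError, match="empty"):
            attachment_centroid(np.empty((0, 3)), "model3_arithmetic")


class TestArchitecture:
    def test_scale_identity_and_geometric_similarity(self):
        row = ArchitectureRow("CFL", 0.1, 0.05, 0.0, 10.0)
        same = scale_architecture(row, 10.0)
        assert same.muscle_mass == pytest.approx(0.1)
        assert same.optimal_fibre_length == pytest.approx(0.05)
        big = scale_architecture(row, 80.0)
        assert big.muscle_mass == pytest.approx(0.8)
        assert big.optimal_fibre_length == pytest.approx(0.1)

    def test_scale_round_trip(self):
        rng = np.random.default_rng(4)
        rows = [ArchitectureRow(f"m{i}", rng.uniform(0.01, 0.1),
                                rng.uniform(0.02, 0.08), 0.0, 10.0)
                for i in range(5)]
        for row in rows:
            back = scale_architecture(scale_architecture(row, 3.7), 10.0)
            assert back.muscle_mass == pytest.approx(row.muscle_mass,
                                                     rel=1e-12)
            assert back.optimal_fibre_length == pytest.approx(
                row.optimal_fibre_length, rel=1e-12)

    def test_fmax_closed_form(self):
        f = fmax_from_mass(0.0106, 0.01, 3e5, 1060.0, 0.0)
        assert f == pytest.approx(300.0, rel=1e-12)

    def test_fmax_inverse_in_fibre_length(self):
        f1 = fmax_from_mass(0.02, 0.03)
        f2 = fmax_from_mass(0.02, 0.06)
        assert f2 == pytest.approx(f1 / 2.0, rel=1e-12)

    def test_extreme_pennation_rejected(self):
        with pytest.raises(ValueError, match="pennation"):
            fmax_from_mass(0.02, 0.03, pennation_deg=90.0)
        with pytest.raises(ValueError, match="positive"):
            fmax_from_mass(0.02, 0.0)

    def test_fmax_scales_as_mass_to_two_thirds(self):
        row = ArchitectureRow("GL", 0.03, 0.03, 0.0, 10.0)
        ratio = 5.0
        f_small = fmax_from_mass(row.muscle_mass, row.optimal_fibre_length)
        scaled = scale_architecture(row, 10.0 * ratio)
        f_big = fmax_from_mass(scaled.muscle_mass, scaled.optimal_fibre_length)
        assert f_big / f_small == pytest.approx(ratio ** (2.0 / 3.0),
                                                rel=1e-12)


def test_group_partition_of_default_muscle_set(full_bundle):
    muscles = full_bundle.muscles()
    assert len(muscles) == 36
    assert set(full_bundle.groups) == set(MUSCLE_GROUPS)
    members = [m for names in full_bundle.groups.values() for m in names]
    assert sorted(members) == sorted(p.name for p in muscles)  # a partition
    assert "IT3" not in full_bundle.groups["knee ext."]
    assert "IT3" in full_bundle.groups["knee flex."]
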