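"""The static-optimization machinery: loads, required moments, the
activation QP, GRF ramping and posture interpolation."""

import numpy as np
import pytest

from _oracles import sample_feasible_points
from bipedsim.mesh import MeshBody
from bipedsim.model import (DoF, JointSpec, Pose, SegmentSpec, SkeletonModel,
                            body_weight_newtons, forward_kinematics,
                            segment_mass_properties, transform_point, GRAVITY)
from bipedsim.muscles import MusclePath, MuscleParameters
from bipedsim.statics import (EquilibriumSystem, ExternalLoad, build_load,
                              build_equilibrium_system,
                              group_mean_activations,
                              interpolate_activation_grid, ramp_grf,
                              required_joint_moments,
                              solve_static_optimization)


class TestBuildLoad:
    def test_vertical_when_angles_zero(self):
        load = build_load(2.0, 0.0, 0.0, np.zeros(3), 100.0)
        assert load.direction == pytest.approx([0.0, 1.0, 0.0])
        assert load.force_vector == pytest.approx([0.0, 200.0, 0.0])

    def test_stated_angles_round_trip(self):
        load = build_load(2.0, 14.0, 8.0, np.zeros(3), 100.0)
        d = load.direction
        assert np.rad2deg(np.arctan2(d[0], d[1])) == pytest.approx(8.0)
        assert np.rad2deg(np.arctan2(-d[2], d[1])) == pytest.approx(14.0)

    def test_zero_magnitude_gives_zero_force(self):
        load = build_load(0.0, 14.0, 8.0, np.zeros(3), 100.0)
        assert np.all(load.force_vector == 0.0)

    def test_out_of_range_angles_rejected(self):
        with pytest.raises(ValueError, match="angles"):
            build_load(1.0, 95.0, 0.0, np.zeros(3), 100.0)


def _toy_limb(moment_arm_m=0.01, with_mass=False):
    """Fixed base + single hinge at the origin + 'foot' child, with one
    muscle at a known perpendicular distance producing negative moment."""
    import trimesh
    meshes = []
    if with_mass:
        box = trimesh.creation.box(extents=[0.02, 0.02, 0.02])
        meshes = [MeshBody(box.vertices + [0.05, 0.0, 0.0], box.faces, 1000.0)]
    segments = [SegmentSpec("base", "ground"),
                SegmentSpec("foot", "hinge", meshes)]
    joints = [JointSpec("ground", None, "base", (0, 0, 0), []),
              JointSpec("hinge", "base", "foot", (0, 0, 0),
                        [DoF("q", (0, 0, 1), "rotation")])]
    model = SkeletonModel(segments, joints)
    muscle = MusclePath("flexor", [("base", (-0.05, -moment_arm_m, 0.0)),
                                   ("foot", (0.05, -moment_arm_m, 0.0))])
    return model, muscle


class TestRequiredMoments:
    def test_grf_through_joint_centre_is_zero(self):
        model, _ = _toy_limb()
        load = ExternalLoad(1.0, np.array([0.0, 1.0, 0.0]), np.zeros(3), 10.0,
                            "foot")
        M = required_joint_moments(model, Pose({"q": 0.0}), load, ["q"],
                                   gravity_on=False)
        assert M["q"] == pytest.approx(0.0, abs=1e-12)

    def test_planar_closed_form(self):
        model, _ = _toy_limb()
        load = ExternalLoad(1.0, np.array([0.0, 1.0, 0.0]),
                            np.array([0.05, 0.0, 0.0]), 10.0, "foot")
        M = required_joint_moments(model, Pose({"q": 0.0}), load, ["q"],
                                   gravity_on=False)
        assert abs(M["q"]) == pytest.approx(0.5, rel=1e-12)

    def test_cop_not_distal_rejected(self):
        model, _ = _toy_limb()
        load = ExternalLoad(1.0, np.array([0.0, 1.0, 0.0]), np.zeros(3), 10.0,
                            "base")
        with pytest.raises(ValueError, match="distal"):
            required_joint_moments(model, Pose({"q": 0.0}), load, ["q"])

    def test_against_virtual_work_oracle(self, reduced_bundle):
        bundle = reduced_bundle
        model = bundle.model
        rng = np.random.default_rng(12)
        pose = model.default_pose(20.0, 35.0)
        for name in ("hip_flexion", "knee_flexion", "tail_prox_pitch"):
            pose.values[name] = float(rng.uniform(-10, 10))
        bw = body_weight_newtons(model)
        load = build_load(2.0, 14.0, 8.0, bundle.cop, bw,
                          bundle.stance_segment)
        M = required_joint_moments(model, pose, load,
                                   bundle.constrained_dofs)

        # independent virtual-work evaluation: M_k = dV/dq_k - F . dx/dq_k
        T0 = forward_kinematics(model, pose)
        cop_local = np.linalg.inv(T0[load.stance_segment]) @ np.append(
            load.cop, 1.0)

        def potential_and_cop(p):
            transforms = forward_kinematics(model, p)
            V = sum(segment_mass_properties(model, s).mass * GRAVITY
                    * transform_point(transforms[s],
                                      segment_mass_properties(model, s).com)[1]
                    for s in model.segments)
            x = (transforms[load.stance_segment] @ cop_local)[:3]
            return V, x

        h = 1e-4  # rad
        for dof in bundle.constrained_dofs:
            q0 = pose.values[dof]
            vp, xp = potential_and_cop(
                pose.with_value(dof, q0 + np.rad2deg(h)))
            vm, xm = potential_and_cop(
                pose.with_value(dof, q0 - np.rad2deg(h)))
            oracle = (vp - vm) / (2 * h) - float(
                load.force_vector @ (xp - xm)) / (2 * h)
            assert M[dof] == pytest.approx(oracle, abs=1e-6), dof


def _system(matrix, b, n_muscles, n_reserves=0):
    n = n_muscles + n_reserves
    matrix = np.asarray(matrix, float)
    return EquilibriumSystem(
        [f"d{i}" for i in range(matrix.shape[0])], matrix,
        np.asarray(b, float),
        np.concatenate([np.zeros(n_muscles), -np.ones(n_reserves)]),
        np.ones(n), [f"m{i}" for i in range(n_muscles)],
        [f"r{i}" for i in range(n_reserves)])


class TestSolveStaticOptimization:
    def test_single_muscle_closed_form(self):
        # M = 0.5 * F_max * r  ->  a = 0.5
        system = _system([[10.0]], [5.0], 1)
        sol = solve_static_optimization(system)
        assert sol.feasible
        assert sol.activations[0] == pytest.approx(0.5, abs=1e-9)

    def test_identical_parallel_muscles_share_equally(self):
        system = _system([[10.0, 10.0]], [10.0], 2)
        sol = solve_static_optimization(system)
        assert sol.activations == pytest.approx([0.5, 0.5], abs=1e-8)

    def test_infeasible_demand_flagged(self):
        system = _system([[10.0]], [20.0], 1)
        sol = solve_static_optimization(system)
        assert not sol.feasible

    @pytest.mark.parametrize("seed", range(4))
    def test_global_optimality_against_sampled_feasible_points(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(4, 8))
        x_true = rng.uniform(0.2, 0.8, size=8)
        b = A @ x_true
        system = _system(A, b, 8)
        sol = solve_static_optimization(system)
        assert sol.feasible
        assert np.abs(sol.residuals).max() < 1e-8 * max(1, np.abs(b).max())
        assert np.all(sol.activations >= -1e-12)
        assert np.all(sol.activations <= 1 + 1e-12)
        pts = sample_feasible_points(A, b, x_true, system.lower, system.upper,
                                     250_000, rng)
        assert len(pts) > 1000
        assert sol.objective <= (pts ** 2).sum(axis=1).min() + 1e-9


class TestRamp:
    def test_toy_capacity_floors_to_step_grid(self):
        # capacity exactly 1.25 BW at 0.1 BW steps -> max 1.2 BW
        model, muscle = _toy_limb(moment_arm_m=0.01)
        bw_n = 10.0
        params = {"flexor": MuscleParameters("flexor", "model3_arithmetic",
                                             62.5, 0.02)}
        load = ExternalLoad(1.0, np.array([0.0, 1.0, 0.0]),
                            np.array([0.05, 0.0, 0.0]), bw_n, "foot")
        res = ramp_grf(model, Pose({"q": 0.0}), [muscle], params, load, ["q"],
                       [], gravity_on=False)
        assert res.max_grf_bw == pytest.approx(1.2)
        assert not res.cap_limited
        assert res.solution.feasible
        assert res.solution.activations[0] == pytest.approx(0.96, abs=1e-6)

    def test_stronger_muscles_never_sustain_less(self):
        model, muscle = _toy_limb()
        load = ExternalLoad(1.0, np.array([0.0, 1.0, 0.0]),
                            np.array([0.05, 0.0, 0.0]), 10.0, "foot")
        maxima = []
        for f_max in (62.5, 625.0):
            params = {"flexor": MuscleParameters(
                "flexor", "model3_arithmetic", f_max, 0.02)}
            res = ramp_grf(model, Pose({"q": 0.0}), [muscle], params, load,
                           ["q"], [], cap_bw=30.0, gravity_on=False)
            maxima.append(res.max_grf_bw)
        assert maxima[1] >= maxima[0]

    def test_capacity_below_first_step_reports_zero(self):
        model, muscle = _toy_limb()
        params = {"flexor": MuscleParameters("flexor", "model3_arithmetic",
                                             1.0, 0.02)}
        load = ExternalLoad(1.0, np.array([0.0, 1.0, 0.0]),
                            np.array([0.05, 0.0, 0.0]), 10.0, "foot")
        res = ramp_grf(model, Pose({"q": 0.0}), [muscle], params, load, ["q"],
                       [], gravity_on=False)
        assert res.max_grf_bw == 0.0
        assert res.solution is None

    def test_cap_limited_flag(self):
        model, muscle = _toy_limb()
        params = {"flexor": MuscleParameters("flexor", "model3_arithmetic",
                                             1e6, 0.02)}
        load = ExternalLoad(1.0, np.array([0.0, 1.0, 0.0]),
                            np.array([0.05, 0.0, 0.0]), 10.0, "foot")
        res = ramp_grf(model, Pose({"q": 0.0}), [muscle], params, load, ["q"],
                       [], cap_bw=2.0, gravity_on=False)
        assert res.cap_limited
        assert res.max_grf_bw == pytest.approx(2.0)

    def test_ramp_is_deterministic(self, reduced_bundle):
        bundle = reduced_bundle
        bw = body_weight_newtons(bundle.model)
        load = build_load(1.0, 14.0, 8.0, bundle.cop, bw,
                          bundle.stance_segment)
        pose = bundle.model.default_pose(25.0, 25.0)
        runs = [ramp_grf(bundle.model, pose, bundle.muscles(),
                         bundle.parameters["model3_arithmetic"], load,
                         bundle.constrained_dofs, bundle.reserves(40.0),
                         groups=bundle.groups) for _ in range(2)]
        assert runs[0].max_grf_bw == runs[1].max_grf_bw
        assert np.array_equal(runs[0].solution.activations,
                              runs[1].solution.activations)


class TestGroupMeans:
    def test_uniform_activations(self):
        sol = solve_static_optimization(_system([[1.0, 1.0]], [1.0], 2))
        means = group_mean_activations(sol, {"g": ["m0", "m1"]})
        assert means["g"] == pytest.approx(0.5, abs=1e-8)

    def test_random_against_direct_arithmetic(self):
        rng = np.random.default_rng(8)
        acts = rng.uniform(size=6)
        from bipedsim.statics import StaticSolution
        sol = StaticSolution(True, acts, np.array([]), float((acts**2).sum()),
                             np.zeros(1), [f"m{i}" for i in range(6)], [])
        groups = {"a": ["m0", "m1", "m2"], "b": ["m3"], "c": []}
        means = group_mean_activations(sol, groups)
        assert means["a"] == pytest.approx(acts[:3].mean())
        assert means["b"] == pytest.approx(acts[3])
        assert np.isnan(means["c"])  # empty group: not available, not 0


class TestActivationInterpolation:
    def test_constant_knots_stay_constant(self):
        out = interpolate_activation_grid(np.full(4, 0.37))
        assert out.shape == (76,)
        assert np.allclose(out, 0.37, atol=1e-12)

    def test_collinear_knots_give_linear_interpolant(self):
        knots = np.array([0.0, 25.0, 50.0, 75.0])
        out = interpolate_activation_grid(0.01 * knots + 0.2)
        grid = np.arange(76.0)
        assert np.allclose(out, 0.01 * grid + 0.2, atol=1e-12)

    def test_cubic_polynomial_reproduced_exactly(self):
        poly = np.polynomial.Polynomial([0.1, -0.02, 3e-4, -2e-6])
        knots = np.array([0.0, 25.0, 50.0, 75.0])
        out = interpolate_activation_grid(poly(knots))
        assert np.abs(out - poly(np.arange(76.0))).max() < 1e-9

    def test_wrong_knots_rejected(self):
        with pytest.raises(ValueError, match="knots"):
            interpolate_activation_grid(np.zeros(3), knots=(0, 25, 50))


def test_equilibrium_residual_on_default_model(full_bundle):
    bundle = full_bundle
    bw = body_weight_newtons(bundle.model)
    load = build_load(1.0, 14.0, 8.0, bundle.cop, bw, bundle.stance_segment)
    pose = bundle.model.default_pose(0.0, 0.0)
    system = build_equilibrium_system(
        bundle.model, pose, bundle.muscles(),
        bundle.parameters["model3_arithmetic"], load,
        bundle.constrained_dofs, bundle.reserves(40.0))
    sol = solve_static_optimization(system)
    assert sol.feasible
    scale = max(1.0, np.abs(system.required_moments).max())
    assert np.abs(sol.residuals).max() < 1e-6 * scale
    assert np.all(sol.activations >= -1e-12)
    assert np.all(sol.activations <= 1 + 1e-12)
    assert np.abs(sol.reserve_activations).max() < 0.95
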