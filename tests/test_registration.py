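"""Landmark SVD registration, transform algebra, and trimmed ICP."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import guidefit as gf
from conftest import random_rigid


def _oracle_rigid_fit(source, target, seeds=5):
    """Independent least-squares rigid fit: numeric minimization over the
    rotation-vector parametrization from several random starts."""

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        src = source @ R.T
        t = target.mean(axis=0) - src.mean(axis=0)
        return np.sum((src + t - target) ** 2)

    rng = np.random.default_rng(0)
    best = None
    for _ in range(seeds):
        res = minimize(cost, rng.normal(scale=1.5, size=3), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    R = Rotation.from_rotvec(best.x).as_matrix()
    t = target.mean(axis=0) - source.mean(axis=0) @ R.T
    return gf.RigidTransform(R, t), best.fun


class TestLandmarkRegister:
    def test_identical_points_give_identity(self, rng):
        pts = rng.normal(size=(5, 3))
        T = gf.landmark_register(gf.LandmarkSet(pts, pts))
        assert T.rotation_angle_deg() < 1e-10
        assert T.translation_norm() < 1e-10

    def test_known_transform_recovered(self, rng):
        src = rng.normal(size=(6, 3)) * 10
        truth = random_rigid(rng)
        T = gf.landmark_register(gf.LandmarkSet(src, truth.apply(src)))
        err = T.compose(truth.inverse())
        assert np.deg2rad(err.rotation_angle_deg()) < 1e-9
        assert err.translation_norm() < 1e-9

    def test_reflection_guard(self, rng):
        # mirrored target: a reflection would fit perfectly, so a nonzero
        # residual under a proper rotation proves the det=+1 guard
        src = rng.normal(size=(4, 3))
        tgt = src.copy()
        tgt[:, 0] *= -1
        T = gf.landmark_register(gf.LandmarkSet(src, tgt))
        assert np.isclose(np.linalg.det(T.rotation), 1.0, atol=1e-9)
        assert np.linalg.norm(T.apply(src) - tgt, axis=1).max() > 1e-6

    @pytest.mark.parametrize("n_points", [3, 5, 10])
    def test_matches_independent_optimizer_on_noisy_pairs(self, rng, n_points):
        src = rng.normal(size=(n_points, 3)) * 5
        truth = random_rigid(rng)
        tgt = truth.apply(src) + rng.normal(scale=0.3, size=(n_points, 3))
        ours = gf.landmark_register(gf.LandmarkSet(src, tgt))
        oracle, oracle_cost = _oracle_rigid_fit(src, tgt)
        our_cost = np.sum((ours.apply(src) - tgt) ** 2)
        assert our_cost <= oracle_cost + 1e-6
        err = ours.compose(oracle.inverse())
        assert err.rotation_angle_deg() < 1e-3
        assert err.translation_norm() < 1e-3

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(gf.DegenerateGeometryError, match="at least 3"):
            gf.LandmarkSet(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        line = np.outer(np.arange(4.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(gf.DegenerateGeometryError, match="collinear"):
            gf.LandmarkSet(line, line)


class TestTransformAlgebra:
    def test_identity_apply(self, rng):
        pts = rng.normal(size=(4, 3))
        assert np.array_equal(gf.RigidTransform.identity().apply(pts), pts)

    def test_apply_then_inverse_is_identity(self, rng):
        T = random_rigid(rng)
        pts = rng.normal(size=(10, 3))
        assert np.allclose(T.inverse().apply(T.apply(pts)), pts, atol=1e-12)

    def test_pure_translation_shifts_centroid(self, small_arch):
        T = gf.RigidTransform(np.eye(3), (0.0, 0.0, 5.0))
        moved = gf.apply_transform(small_arch, T)
        shift = moved.vertices.mean(axis=0) - small_arch.vertices.mean(axis=0)
        assert np.allclose(shift, (0, 0, 5), atol=1e-12)

    def test_compose_identity_neutral(self, rng):
        a = random_rigid(rng)
        ident = gf.RigidTransform.identity()
        c = ident.compose(a)
        assert np.allclose(c.rotation, a.rotation)
        assert np.allclose(c.translation, a.translation)

    def test_double_inverse(self, rng):
        a = random_rigid(rng)
        b = a.inverse().inverse()
        assert np.allclose(b.rotation, a.rotation, atol=1e-12)
        assert np.allclose(b.translation, a.translation, atol=1e-12)

    def test_quarter_turns_compose_to_half_turn(self):
        q = gf.RigidTransform.from_axis_angle((0, 0, 1), 90.0)
        h = q.compose(q)
        expected = gf.RigidTransform.from_axis_angle((0, 0, 1), 180.0)
        assert np.allclose(h.rotation, expected.rotation, atol=1e-12)

    def test_order_of_composition(self, rng):
        a, b = random_rigid(rng), random_rigid(rng)
        pts = rng.normal(size=(5, 3))
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-12)


class TestICP:
    def test_already_aligned_is_fixed_point(self, small_arch):
        res = gf.icp_refine(small_arch, small_arch, params=gf.ICPParams(sample_count=2000, seed=0))
        assert res.converged
        assert res.transform.rotation_angle_deg() < 1e-9
        assert res.transform.translation_norm() < 1e-9
        assert res.final_rms < 1e-9

    def test_recovers_small_perturbation(self, default_arch):
        pert = gf.RigidTransform.from_axis_angle((0, 0, 1), 5.0, (2.0, 0.0, 0.0))
        moving = gf.apply_transform(default_arch, pert)
        res = gf.icp_refine(moving, default_arch, params=gf.ICPParams(sample_count=3000, seed=0))
        err = res.transform.compose(pert)
        assert err.rotation_angle_deg() < 0.05
        assert err.translation_norm() < 0.02
        assert res.final_rms < 1e-3

    def test_noise_floor_rms(self, small_arch):
        sigma = 0.05
        pose = gf.RigidTransform.from_axis_angle((0.1, 0.2, 1.0), 4.0, (1.0, -1.0, 2.0))
        noisy = gf.simulate_optical_scan(small_arch, 3000, sigma, pose, seed=9)
        # initialize near truth: align the noisy scan back onto the template
        res = gf.icp_refine(noisy, small_arch, init=pose.inverse(),
                            params=gf.ICPParams(sample_count=3000, seed=0))
        assert 0.8 * sigma <= res.final_rms <= 1.2 * sigma

    def test_invariant_under_common_rigid_motion(self, small_arch, rng):
        # conjugation identity: moving both meshes by G conjugates the result
        pert = gf.RigidTransform.from_axis_angle((0, 1, 0), 3.0, (1.0, 0.5, 0.0))
        moving = gf.apply_transform(small_arch, pert)
        params = gf.ICPParams(sample_count=2000, seed=3, max_iterations=30)
        base = gf.icp_refine(moving, small_arch, params=params)
        G = random_rigid(rng, max_angle_deg=40.0, max_translation=5.0)
        res_g = gf.icp_refine(
            gf.apply_transform(moving, G), gf.apply_transform(small_arch, G), params=params
        )
        conj = G.compose(base.transform).compose(G.inverse())
        err = res_g.transform.compose(conj.inverse())
        assert err.rotation_angle_deg() < 1e-5
        assert err.translation_norm() < 1e-5

    def test_returned_transform_is_proper(self, small_arch):
        pert = gf.RigidTransform.from_axis_angle((1, 0, 0), 2.0, (0.5, 0.5, 0.5))
        res = gf.icp_refine(gf.apply_transform(small_arch, pert), small_arch,
                            params=gf.ICPParams(sample_count=1000, seed=0, max_iterations=10))
        R = res.transform.rotation
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)
        assert np.isclose(np.linalg.det(R), 1.0, atol=1e-9)

    def test_poor_overlap_warns(self, small_arch):
        far = gf.RigidTransform(np.eye(3), (200.0, 0.0, 0.0))
        moving = gf.apply_transform(small_arch, far)
        with pytest.warns(UserWarning, match="overlap"):
            gf.icp_refine(moving, small_arch,
                          params=gf.ICPParams(sample_count=500, seed=0, max_iterations=1))

    def test_rms_trace_recorded(self, small_arch):
        pert = gf.RigidTransform.from_axis_angle((0, 0, 1), 3.0, (1.0, 0.0, 0.0))
        res = gf.icp_refine(gf.apply_transform(small_arch, pert), small_arch,
                            params=gf.ICPParams(sample_count=2000, seed=0))
        assert len(res.rms_trace) >= 2
        assert res.rms_trace[-1] <= res.rms_trace[0]


class TestLandmarkFiles:
    def test_round_trip_with_comments(self, tmp_path, rng):
        lm = gf.LandmarkSet(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))
        path = tmp_path / "lm.txt"
        gf.write_landmarks(path, lm)
        back = gf.read_landmarks(path)
        assert np.allclose(back.source_points, lm.source_points, atol=1e-8)
        assert np.allclose(back.target_points, lm.target_points, atol=1e-8)

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "lm.txt"
        path.write_text("1 2 3 4 5\n")
        with pytest.raises(gf.ParameterError, match="expected 6"):
            gf.read_landmarks(path)
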