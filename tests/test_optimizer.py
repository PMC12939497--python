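"""Objective, constraints, the SQP solver, and its brute-force oracle."""

import numpy as np
import pytest

import isopoint as ip
from isopoint.optimizer import objective_batch, objective_grad

from conftest import random_rigid


class TestObjective:
    def test_equidistant_targets_give_zero(self, rng):
        p = np.array([1.0, -2.0, 3.0])
        v = rng.normal(size=(20, 3))
        targets = p + 7.5 * v / np.linalg.norm(v, axis=1, keepdims=True)
        assert ip.objective_f(p, targets) < 1e-24

    def test_hand_computed_variance(self):
        # distances {1, 3}, mean 2, population variance 1.0
        f = ip.objective_f((0, 0, 0), [(1, 0, 0), (3, 0, 0)])
        assert f == pytest.approx(1.0, abs=1e-12)

    def test_rigid_invariance(self, rng):
        p = rng.normal(size=3)
        targets = rng.normal(scale=30, size=(15, 3))
        R, t = random_rigid(rng)
        f0 = ip.objective_f(p, targets)
        f1 = ip.objective_f(R @ p + t, targets @ R.T + t)
        assert f0 == pytest.approx(f1, rel=1e-9)

    def test_too_few_targets_raise(self):
        with pytest.raises(ValueError):
            ip.objective_f((0, 0, 0), [(1, 0, 0)])

    def test_batch_matches_scalar(self, rng):
        targets = rng.normal(scale=20, size=(12, 3))
        pts = rng.normal(scale=5, size=(8, 3))
        batch = objective_batch(pts, targets)
        for p, fb in zip(pts, batch):
            assert fb == pytest.approx(ip.objective_f(p, targets), rel=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        targets = rng.normal(scale=20, size=(10, 3))
        p = rng.normal(scale=5, size=3)
        g = objective_grad(p, targets)
        h = 1e-6
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            fd = (ip.objective_f(p + e, targets) - ip.objective_f(p - e, targets)) / (2 * h)
            assert g[k] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestConstraints:
    def test_annulus_centre_infeasible(self, knee_problem):
        prob = knee_problem["problem"]
        g = ip.constraints_g(prob.s_point, prob)
        assert g[0] == pytest.approx(prob.r_min)

    def test_mid_annulus_surface_vertex_feasible(self, knee_problem):
        prob = knee_problem["problem"]
        idx = prob.annulus_vertices()
        d = np.linalg.norm(prob.surface.vertices[idx] - prob.s_point, axis=1)
        v = prob.surface.vertices[idx[np.argmin(np.abs(d - 10.0))]]
        g = ip.constraints_g(v, prob)
        assert np.all(g <= 0)
        assert g[2] == pytest.approx(-prob.surface_tolerance, abs=1e-9)

    def test_outer_boundary_active(self, knee_problem):
        prob = knee_problem["problem"]
        direction = np.array([0.0, 0.0, 1.0])
        p = prob.s_point + prob.r_max * direction
        g = ip.constraints_g(p, prob)
        assert g[1] == pytest.approx(0.0, abs=1e-9)


class TestBruteForce:
    def test_planted_vertex_is_found(self, knee_problem):
        prob = knee_problem["problem"]
        truth = knee_problem["truth"]
        pt, f = ip.brute_force_ipoint(prob)
        assert np.linalg.norm(pt - truth.p_star_local) < 1e-6
        assert f < 1e-12

    def test_two_candidates_hand_computed(self):
        # a tiny two-triangle strip: vertex (0,0,0) sees distances {1,3}
        # (f=1.0); vertex (2,0,0) sees {1,1} (f=0): the latter must win
        v = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [1.0, 1.0, 0.0], [1.0, -1.0, 0.0]])
        t = [[0, 2, 3], [1, 2, 3]]
        surf = ip.surface_from_mesh(v, t)
        targets = np.array([[1.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        prob = ip.OptimizationProblem(
            targets=targets, s_point=(1.0, 8.0, 0.0), surface=surf,
            r_min=5.0, r_max=15.0,
        )
        pt, f = ip.brute_force_ipoint(prob)
        assert np.allclose(pt, [2, 0, 0])
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_empty_annulus_raises(self, knee_problem):
        prob = knee_problem["problem"]
        far = ip.OptimizationProblem(
            targets=prob.targets,
            s_point=prob.s_point + 500.0,
            surface=prob.surface,
        )
        with pytest.raises(ip.InfeasibleProblemError):
            ip.brute_force_ipoint(far)


class TestSeeding:
    def test_k1_is_argmin_vertex(self, knee_problem):
        prob = knee_problem["problem"]
        seeds = ip.seed_candidates(prob, 1)
        best, _ = ip.brute_force_ipoint(prob)
        assert np.allclose(seeds[0], best)

    def test_k_clamped_to_annulus_count(self, knee_problem):
        prob = knee_problem["problem"]
        n_annulus = len(prob.annulus_vertices())
        seeds = ip.seed_candidates(prob, n_annulus + 50)
        assert n_annulus <= len(seeds) <= n_annulus + 1  # + projected landmark

    def test_multistart_never_worse_than_single(self, knee_problem):
        prob = knee_problem["problem"]
        f1 = ip.optimize_ipoint(prob, n_starts=1).objective
        f5 = ip.optimize_ipoint(prob, n_starts=5).objective
        assert f5 <= f1 + 1e-12


class TestSqpSolve:
    def test_planted_point_recovered(self, knee_problem):
        prob = knee_problem["problem"]
        truth = knee_problem["truth"]
        res = ip.optimize_ipoint(prob, n_starts=5)
        assert res.converged
        assert np.linalg.norm(res.i_point - truth.p_star_local) < 0.5
        assert res.objective < 1e-6
        r = np.linalg.norm(res.i_point - prob.s_point)
        assert prob.r_min - 1e-6 <= r <= prob.r_max + 1e-6
        assert res.max_constraint_violation <= prob.surface_tolerance

    def test_objective_never_above_vertex_oracle(self):
        for seed in range(5):
            seq, surface, lm, truth = ip.make_knee(ip.SyntheticSpec(seed=100 + seed))
            prob, _, _ = ip.build_problem(seq, lm)
            assert len(prob.surface.vertices) <= 2000
            res = ip.optimize_ipoint(prob, n_starts=5)
            _, f_bf = ip.brute_force_ipoint(prob)
            assert res.objective <= f_bf + 1e-9

    def test_restart_from_solution_is_fixed_point(self, knee_problem):
        prob = knee_problem["problem"]
        res = ip.optimize_ipoint(prob, n_starts=3)
        prob2 = ip.OptimizationProblem(
            targets=prob.targets, s_point=prob.s_point, surface=prob.surface,
            initial_point=res.i_point,
        )
        res2 = ip.sqp_solve(prob2)
        assert abs(res2.objective - res.objective) < 1e-10

    def test_noise_robustness_sd_near_sigma(self):
        sigma = 0.5
        ok = 0
        for seed in range(10):
            seq, surface, lm, truth = ip.make_knee(
                ip.SyntheticSpec(seed=200 + seed, noise_sd=sigma)
            )
            prob, _, _ = ip.build_problem(seq, lm)
            res = ip.optimize_ipoint(prob, n_starts=4)
            ok += 0.5 * sigma <= res.length_sd <= 1.5 * sigma
        assert ok >= 9

    def test_rigid_invariance_of_solution_objective(self, rng):
        seq, surface, lm, truth = ip.make_knee(ip.SyntheticSpec(seed=7, apply_pose=False))
        prob, _, _ = ip.build_problem(seq, lm)
        res = ip.optimize_ipoint(prob, n_starts=3)
        R, t = random_rigid(rng)
        surf_t = ip.SurfaceModel(
            vertices=prob.surface.vertices @ R.T + t,
            triangles=prob.surface.triangles,
        )
        prob_t = ip.OptimizationProblem(
            targets=prob.targets @ R.T + t,
            s_point=R @ prob.s_point + t,
            surface=surf_t,
        )
        res_t = ip.optimize_ipoint(prob_t, n_starts=3)
        assert res_t.objective == pytest.approx(res.objective, abs=1e-8)

    def test_infeasible_problem_raises(self, knee_problem):
        prob = knee_problem["problem"]
        bad = ip.OptimizationProblem(
            targets=prob.targets, s_point=prob.s_point + 500.0, surface=prob.surface,
        )
        with pytest.raises(ip.InfeasibleProblemError):
            ip.optimize_ipoint(bad)
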