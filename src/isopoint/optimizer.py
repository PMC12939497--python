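"""Constrained search for the individualized femoral attachment (I-point).

The attachment candidate ``P`` is scored by the population variance of its
straight-line distances to the per-frame patellar centroids ``C_i``,

    f(P) = (1/N) * sum_i ( ||P - C_i|| - mean_j ||P - C_j|| )^2    [mm^2]

i.e. the squared standard deviation of the modeled ligament length over
the motion.  ``P`` is constrained to lie (within a small tolerance) on the
femoral surface and inside a 5-15 mm annulus around the conventional
Schottle landmark.  The program is solved by sequential quadratic
programming: at each iterate a QP with linearized constraints yields a
step, accepted through an l1-merit backtracking line search, with a
damped-BFGS curvature model.  A vertex-exhaustive search over the annulus
provides both the multi-start seeds and an independent lower-bound oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .geometry import SurfaceModel, project_to_surface


class InfeasibleProblemError(ValueError):
    """No part of the femoral surface lies inside the annulus."""


# ---------------------------------------------------------------------------
# Problem / result containers


@dataclass
class OptimizationProblem:
    """The attachment-point program: targets, annulus, surface.

    All coordinates share one (local anatomical) frame, in mm.
    """

    targets: np.ndarray  # (N, 3) per-frame patellar centroids
    s_point: np.ndarray  # annulus centre
    surface: SurfaceModel
    r_min: float = 5.0
    r_max: float = 15.0
    surface_tolerance: float = 0.1  # mm
    initial_point: np.ndarray | None = None

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=float).reshape(-1, 3)
        self.s_point = np.asarray(self.s_point, dtype=float).reshape(3)
        if len(self.targets) < 2:
            raise ValueError("need at least 2 target frames")
        if not self.r_min < self.r_max:
            raise ValueError("r_min must be < r_max")
        if self.initial_point is not None:
            self.initial_point = np.asarray(self.initial_point, dtype=float).reshape(3)

    def annulus_vertices(self) -> np.ndarray:
        """Indices of surface vertices inside the annulus."""
        d = np.linalg.norm(self.surface.vertices - self.s_point, axis=1)
        return np.flatnonzero((d >= self.r_min) & (d <= self.r_max))


@dataclass
class OptimizationResult:
    """Solution of the attachment program."""

    i_point: np.ndarray
    objective: float  # f, mm^2 (length variance)
    length_sd: float  # sqrt(f), mm
    mean_length: float  # mm
    iterations: int
    converged: bool
    max_constraint_violation: float
    seeds_evaluated: int = 1

    def to_dict(self) -> dict:
        return {
            "i_point": [float(v) for v in self.i_point],
            "objective_mm2": float(self.objective),
            "length_sd_mm": float(self.length_sd),
            "mean_length_mm": float(self.mean_length),
            "iterations": int(self.iterations),
            "converged": bool(self.converged),
            "max_constraint_violation_mm": float(self.max_constraint_violation),
            "seeds_evaluated": int(self.seeds_evaluated),
        }


# ---------------------------------------------------------------------------
# Objective and constraints


def objective_f(p, targets) -> float:
    """Length variance (mm^2) of ``p`` against the target centroids."""
    targets = np.asarray(targets, dtype=float).reshape(-1, 3)
    if len(targets) < 2:
        raise ValueError("need at least 2 targets")
    d = np.linalg.norm(np.asarray(p, dtype=float) - targets, axis=1)
    return float(np.mean((d - d.mean()) ** 2))


def objective_batch(points, targets) -> np.ndarray:
    """Vectorized length variance for many candidate points."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    d = np.linalg.norm(points[:, None, :] - targets[None, :, :], axis=2)
    return ((d - d.mean(axis=1, keepdims=True)) ** 2).mean(axis=1)


def objective_grad(p, targets) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    diff = p - targets
    d = np.linalg.norm(diff, axis=1)
    d = np.maximum(d, 1e-12)
    u = diff / d[:, None]
    return (2.0 / len(targets)) * ((d - d.mean()) @ u)


def constraints_g(p, problem: OptimizationProblem) -> np.ndarray:
    """Inequality constraints g(P) <= 0 at feasibility.

    ``[r_min - ||P - S||, ||P - S|| - r_max, dist_to_surface(P) - eps]``.
    """
    p = np.asarray(p, dtype=float)
    r = float(np.linalg.norm(p - problem.s_point))
    dist = project_to_surface(problem.surface, p)[1]
    return np.array(
        [problem.r_min - r, r - problem.r_max, dist - problem.surface_tolerance]
    )


def _constraints_and_grads(p, problem):
    p = np.asarray(p, dtype=float)
    rv = p - problem.s_point
    r = float(np.linalg.norm(rv))
    ur = rv / r if r > 1e-12 else np.array([1.0, 0.0, 0.0])
    closest, dist, _ = project_to_surface(problem.surface, p)
    if dist > 1e-8:
        gdist = (p - closest) / dist
    else:
        # at the surface the unsigned distance is non-smooth; central
        # finite differences give a usable subgradient there
        h = 1e-5
        gdist = np.zeros(3)
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            dp = project_to_surface(problem.surface, p + e)[1]
            dm = project_to_surface(problem.surface, p - e)[1]
            gdist[k] = (dp - dm) / (2 * h)
    g = np.array(
        [problem.r_min - r, r - problem.r_max, dist - problem.surface_tolerance]
    )
    grads = np.vstack([-ur, ur, gdist])
    return g, grads


# ---------------------------------------------------------------------------
# Brute-force oracle and seeding


def brute_force_ipoint(problem: OptimizationProblem) -> tuple[np.ndarray, float]:
    """Exhaustive minimum of f over annulus surface vertices.

    Deterministic independent oracle: every vertex whose distance to the
    Schottle landmark lies in [r_min, r_max] is scored; ties break towards
    the smallest distance to the landmark, then lexicographically.
    """
    idx = problem.annulus_vertices()
    if len(idx) == 0:
        raise InfeasibleProblemError("no surface vertex inside the annulus")
    verts = problem.surface.vertices[idx]
    f = objective_batch(verts, problem.targets)
    order = _tie_break_order(verts, f, problem.s_point)
    best = order[0]
    return verts[best].copy(), float(f[best])


def _tie_break_order(points, f, s_point, tol=1e-12):
    """Sort by objective, breaking near-ties by ||P-S|| then lexicographic."""
    r = np.linalg.norm(points - s_point, axis=1)
    fkey = np.round(f / tol) * tol
    return np.lexsort((points[:, 2], points[:, 1], points[:, 0], r, fkey))


def seed_candidates(problem: OptimizationProblem, k: int = 10) -> np.ndarray:
    """The k best annulus vertices (plus the projected landmark if feasible).

    These seed the multi-start SQP; k larger than the annulus vertex count
    simply returns them all.
    """
    idx = problem.annulus_vertices()
    if len(idx) == 0:
        raise InfeasibleProblemError("no surface vertex inside the annulus")
    verts = problem.surface.vertices[idx]
    f = objective_batch(verts, problem.targets)
    order = _tie_break_order(verts, f, problem.s_point)
    seeds = [verts[i] for i in order[: min(k, len(order))]]
    proj = project_to_surface(problem.surface, problem.s_point)[0]
    r = np.linalg.norm(proj - problem.s_point)
    if problem.r_min <= r <= problem.r_max:
        seeds.append(proj)
    out, seen = [], set()
    for s in seeds:
        key = tuple(np.round(s, 9))
        if key not in seen:
            seen.add(key)
            out.append(s)
    return np.array(out)


# ---------------------------------------------------------------------------
# QP subproblem: 3 variables, few linear inequality constraints


def _solve_qp(H, c, A, b):
    """min 0.5 d'Hd + c'd  s.t.  A d <= b, by active-set enumeration.

    With at most three constraints every active set can be enumerated;
    returns (d, lambda) or (None, None) if the linearization is infeasible.
    """
    m = len(b)
    best = None
    for size in range(0, m + 1):
        for active in itertools.combinations(range(m), size):
            Aa = A[list(active)]
            n = 3 + size
            K = np.zeros((n, n))
            K[:3, :3] = H
            if size:
                K[:3, 3:] = Aa.T
                K[3:, :3] = Aa
            rhs = np.concatenate([-c, b[list(active)]])
            try:
                sol = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError:
                continue
            d = sol[:3]
            lam = np.zeros(m)
            lam[list(active)] = sol[3:]
            if np.any(lam < -1e-9):
                continue
            if np.any(A @ d - b > 1e-8):
                continue
            val = 0.5 * d @ H @ d + c @ d
            if best is None or val < best[0] - 1e-15:
                best = (val, d, np.maximum(lam, 0.0))
    if best is None:
        return None, None
    return best[1], best[2]


def _restore_feasibility(p, problem):
    """Alternate surface projection and radial clamping onto the annulus."""
    q = np.asarray(p, dtype=float).copy()
    for _ in range(20):
        q = project_to_surface(problem.surface, q)[0]
        rv = q - problem.s_point
        r = np.linalg.norm(rv)
        if r < problem.r_min - 1e-9:
            q = problem.s_point + rv * (problem.r_min / max(r, 1e-12))
        elif r > problem.r_max + 1e-9:
            q = problem.s_point + rv * (problem.r_max / r)
        else:
            q = project_to_surface(problem.surface, q)[0]
            break
    return q


def _result_at(p, problem, iterations, converged, seeds=1):
    d = np.linalg.norm(p - problem.targets, axis=1)
    f = float(np.mean((d - d.mean()) ** 2))
    g = constraints_g(p, problem)
    viol = float(np.maximum(g, 0.0).max())
    return OptimizationResult(
        i_point=np.asarray(p, dtype=float).copy(),
        objective=f,
        length_sd=float(np.sqrt(f)),
        mean_length=float(d.mean()),
        iterations=iterations,
        converged=converged,
        max_constraint_violation=viol,
        seeds_evaluated=seeds,
    )


def sqp_solve(
    problem: OptimizationProblem,
    tol_f: float = 1e-10,
    tol_kkt: float = 1e-6,
    max_iter: int = 200,
) -> OptimizationResult:
    """Solve the attachment program by SQP from ``problem.initial_point``.

    Each iteration linearizes the constraints, solves the 3-variable QP
    under a damped-BFGS Hessian model, and accepts the step via an l1
    merit backtracking search.  The final iterate is projected exactly
    onto the surface and re-checked for feasibility; the returned point is
    never worse (in f, among feasible points seen) than the start.
    """
    if problem.initial_point is not None:
        x = problem.initial_point.astype(float).copy()
    else:
        x = seed_candidates(problem, 1)[0].copy()
    if len(problem.annulus_vertices()) == 0:
        raise InfeasibleProblemError("no surface vertex inside the annulus")

    targets = problem.targets
    H = np.eye(3)
    mu = 1.0
    g, G = _constraints_and_grads(x, problem)
    grad = objective_grad(x, targets)
    f = objective_f(x, targets)

    best_feasible = None
    if np.all(g <= 1e-9):
        best_feasible = (f, x.copy())

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d, lam = _solve_qp(H, grad, G, -g)
        if d is None:
            # linearization infeasible: restore and restart curvature
            x = _restore_feasibility(x, problem)
            H = np.eye(3)
            g, G = _constraints_and_grads(x, problem)
            grad = objective_grad(x, targets)
            f = objective_f(x, targets)
            continue

        kkt = np.linalg.norm(grad + lam @ G) + float(
            np.abs(lam * g).sum() + np.maximum(g, 0.0).sum()
        )
        if kkt < tol_kkt and np.linalg.norm(d) < 1e-8:
            converged = True
            break

        mu = max(mu, 2.0 * float(np.abs(lam).max()) + 1.0)
        viol = float(np.maximum(g, 0.0).sum())
        merit0 = f + mu * viol
        ddir = float(grad @ d) - mu * viol

        alpha, accepted = 1.0, False
        for _ in range(40):
            xn = x + alpha * d
            fn = objective_f(xn, targets)
            gn = constraints_g(xn, problem)
            merit = fn + mu * float(np.maximum(gn, 0.0).sum())
            if merit <= merit0 + 1e-4 * alpha * ddir or merit < merit0 - 1e-14:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            converged = abs(ddir) < tol_kkt
            break

        gn, Gn = _constraints_and_grads(xn, problem)
        gradn = objective_grad(xn, targets)
        # damped BFGS (Powell) on the Lagrangian gradient difference
        s = xn - x
        y = (gradn + lam @ Gn) - (grad + lam @ G)
        sHs = float(s @ H @ s)
        sy = float(s @ y)
        if sHs > 1e-16:
            if sy < 0.2 * sHs:
                theta = 0.8 * sHs / (sHs - sy)
                y = theta * y + (1.0 - theta) * (H @ s)
                sy = float(s @ y)
            if sy > 1e-16:
                Hs = H @ s
                H = H - np.outer(Hs, Hs) / sHs + np.outer(y, y) / sy
        fprev = f
        x, f, g, G, grad = xn, fn, gn, Gn, gradn
        if np.all(g <= 1e-9) and (best_feasible is None or f < best_feasible[0]):
            best_feasible = (f, x.copy())
        if abs(f - fprev) < tol_f and kkt < tol_kkt:
            converged = True
            break

    # exact surface projection of the final iterate, then feasibility check
    x_final = _restore_feasibility(x, problem)
    f_final = objective_f(x_final, targets)
    g_final = constraints_g(x_final, problem)
    if np.all(g_final <= 1e-6) and (
        best_feasible is None or f_final < best_feasible[0]
    ):
        best_feasible = (f_final, x_final)

    if best_feasible is None:
        return _result_at(x_final, problem, it, False)
    res = _result_at(best_feasible[1], problem, it, converged)
    return res


def optimize_ipoint(
    problem: OptimizationProblem,
    n_starts: int = 10,
    tol_f: float = 1e-10,
    tol_kkt: float = 1e-6,
    max_iter: int = 200,
) -> OptimizationResult:
    """Multi-start driver: run SQP from the best annulus seeds, keep the best.

    Ties in the final objective break towards the smallest distance to the
    Schottle landmark, then lexicographic coordinates, for determinism.
    """
    seeds = seed_candidates(problem, n_starts)
    results = []
    total_iters = 0
    for s in seeds:
        sub = OptimizationProblem(
            targets=problem.targets,
            s_point=problem.s_point,
            surface=problem.surface,
            r_min=problem.r_min,
            r_max=problem.r_max,
            surface_tolerance=problem.surface_tolerance,
            initial_point=s,
        )
        r = sqp_solve(sub, tol_f=tol_f, tol_kkt=tol_kkt, max_iter=max_iter)
        total_iters += r.iterations
        results.append(r)
    pts = np.array([r.i_point for r in results])
    fs = np.array([r.objective for r in results])
    order = _tie_break_order(pts, fs, problem.s_point)
    best = results[order[0]]
    best.seeds_evaluated = len(seeds)
    best.iterations = total_iters
    return best
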