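"""Independent brute-force oracles used only by the tests.

Both oracles work by exhaustive enumeration of candidate active sets, so
they share no code path with the package's iterative solvers:

* the LP oracle enumerates vertices (n-subsets of constraint hyperplanes);
* the QP oracle solves the KKT system of every candidate active set and
  takes the best feasible stationary point, which for a strictly convex
  objective is the exact global optimum.
"""

from __future__ import annotations

import itertools

import numpy as np

from dietopt.core import ConstraintSystem


def _hyperplanes(system: ConstraintSystem) -> list[tuple[np.ndarray, float]]:
    planes = []
    n = system.n_foods
    for k in range(system.A_in.shape[0]):
        if np.isfinite(system.lower[k]):
            planes.append((system.A_in[k], float(system.lower[k])))
        if np.isfinite(system.upper[k]):
            planes.append((system.A_in[k], float(system.upper[k])))
    eye = np.eye(n)
    for i in range(n):
        if np.isfinite(system.x_lower[i]):
            planes.append((eye[i], float(system.x_lower[i])))
        if np.isfinite(system.x_upper[i]):
            planes.append((eye[i], float(system.x_upper[i])))
    return planes


def _feasible(system: ConstraintSystem, x: np.ndarray, tol: float = 1e-7) -> bool:
    if system.A_eq.size and np.max(np.abs(system.A_eq @ x - system.b_eq)) > tol:
        return False
    if system.A_in.size:
        v = system.A_in @ x
        if np.any(v < system.lower - tol) or np.any(v > system.upper + tol):
            return False
    return bool(np.all(x >= system.x_lower - tol) and np.all(x <= system.x_upper + tol))


def lp_vertex_enumeration(system: ConstraintSystem, c: np.ndarray):
    """Optimal (objective, x) of min c.x by enumerating basic feasible points."""
    n = system.n_foods
    m_eq = system.A_eq.shape[0]
    planes = _hyperplanes(system)
    best, best_x = np.inf, None
    for combo in itertools.combinations(range(len(planes)), n - m_eq):
        a = np.vstack([system.A_eq] + [planes[k][0][None, :] for k in combo]) if m_eq else (
            np.vstack([planes[k][0] for k in combo]) if combo else np.zeros((0, n)))
        b = np.concatenate([system.b_eq, [planes[k][1] for k in combo]])
        if a.shape[0] != n or np.linalg.matrix_rank(a) < n:
            continue
        try:
            x = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            continue
        if _feasible(system, x):
            val = float(c @ x)
            if val < best:
                best, best_x = val, x
    return best, best_x


def qp_active_set_enumeration(system: ConstraintSystem, x0: np.ndarray):
    """Exact optimum of min sum((x-x0)/x0)^2 over the system, via KKT
    enumeration over all candidate active sets."""
    n = system.n_foods
    h = np.diag(2.0 / x0**2)
    planes = _hyperplanes(system)
    m_eq = system.A_eq.shape[0]
    best, best_x = np.inf, None
    for size in range(0, n - m_eq + 1):
        for combo in itertools.combinations(range(len(planes)), size):
            rows = [system.A_eq] if m_eq else []
            rows += [planes[k][0][None, :] for k in combo]
            a = np.vstack(rows) if rows else np.zeros((0, n))
            b = np.concatenate([system.b_eq, [planes[k][1] for k in combo]])
            m = a.shape[0]
            kkt = np.block([[h, a.T], [a, np.zeros((m, m))]])
            rhs = np.concatenate([h @ x0, b])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            x = sol[:n]
            if _feasible(system, x):
                val = float(np.sum(((x - x0) / x0) ** 2))
                if val < best:
                    best, best_x = val, x
    return best, best_x


def random_feasible_system(
    rng: np.random.Generator,
    n_foods: int,
    n_rows: int,
    n_finite_uppers: int = 2,
) -> tuple[ConstraintSystem, np.ndarray]:
    """A random compact system guaranteed nonempty (built around a feasible
    point), with an energy-like equality, two-sided rows, and box bounds."""
    x_feas = rng.uniform(0.5, 3.0, n_foods)
    system = ConstraintSystem([f"f{i}" for i in range(n_foods)])
    e = rng.uniform(0.5, 2.0, n_foods)
    system.add_equality(e, float(e @ x_feas), "energy")
    for k in range(n_rows):
        a = rng.normal(0.0, 1.0, n_foods)
        v = float(a @ x_feas)
        lo = v - rng.uniform(0.1, 2.0)
        hi = v + rng.uniform(0.1, 2.0)
        system.add_inequality(a, lo, hi, f"nutrient:n{k}")
    upper = np.full(n_foods, np.inf)
    for i in rng.choice(n_foods, size=min(n_finite_uppers, n_foods), replace=False):
        upper[i] = x_feas[i] + rng.uniform(0.5, 2.0)
    system.set_variable_bounds(np.zeros(n_foods), upper)
    return system, x_feas
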