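"""Solvers for the two diet-optimization problems.

The minimum-cost model is a linear program solved with HiGHS through
:func:`scipy.optimize.linprog`.  The minimum-deviation model minimizes the
sum of squared relative deviations from the baseline diet,

    min_x  sum_i ((x_i - x0_i) / x0_i)^2,

a strictly convex quadratic program with diagonal positive-definite
curvature ``2 / x0_i^2`` — its solution is the unique global minimum.  It is
solved in the original variables with :func:`scipy.optimize.minimize`
(``trust-constr`` by default, ``SLSQP`` as an alternative back-end used for
cross-checking uniqueness).

All returned solutions are audited: totals are recomputed from the solution
vector, feasibility is re-verified against the assembled system, and the
binding-constraint set is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from .constraints import BuilderConfig, build
from .core import (
    FEASIBILITY_TOL,
    ConstraintSystem,
    DietSolution,
    FoodUniverse,
    PopulationGroup,
    Scenario,
    solution_totals,
    verify_solution,
)


@dataclass
class SolverSettings:
    feasibility_tol: float = FEASIBILITY_TOL
    optimality_tol: float = 1e-9
    max_iter: int = 500
    qp_backend: str = "trust-constr"  # or "slsqp"

    def __post_init__(self) -> None:
        if self.feasibility_tol <= 0 or self.optimality_tol <= 0:
            raise ValueError("tolerances must be positive")


def _split_inequalities(system: ConstraintSystem):
    """Two-sided rows -> one-sided A_ub x <= b_ub form for linprog."""
    blocks_a, blocks_b = [], []
    finite_up = np.isfinite(system.upper)
    if finite_up.any():
        blocks_a.append(system.A_in[finite_up])
        blocks_b.append(system.upper[finite_up])
    finite_lo = np.isfinite(system.lower)
    if finite_lo.any():
        blocks_a.append(-system.A_in[finite_lo])
        blocks_b.append(-system.lower[finite_lo])
    if not blocks_a:
        return None, None
    return np.vstack(blocks_a), np.concatenate(blocks_b)


def _family(label: str) -> str:
    return label.split(":", 1)[0]


def _families(system: ConstraintSystem) -> list[str]:
    fams = []
    for lab in system.eq_labels + system.in_labels:
        f = _family(lab)
        if f not in fams:
            fams.append(f)
    if np.any(system.x_lower > 0) or np.any(np.isfinite(system.x_upper)):
        fams.append("habit")
    return fams


def _relax_family(system: ConstraintSystem, family: str) -> ConstraintSystem:
    """Copy of the system with every row of one constraint family dropped."""
    relaxed = ConstraintSystem(system.food_ids)
    for k, lab in enumerate(system.eq_labels):
        if _family(lab) != family:
            relaxed.add_equality(system.A_eq[k], system.b_eq[k], lab)
    for k, lab in enumerate(system.in_labels):
        if _family(lab) != family:
            relaxed.add_inequality(system.A_in[k], system.lower[k], system.upper[k], lab)
    if family != "habit":
        relaxed.set_variable_bounds(system.x_lower, system.x_upper)
    return relaxed


def _feasible_point(system: ConstraintSystem) -> bool:
    """Cheap phase-1 feasibility check via a zero-objective LP."""
    a_ub, b_ub = _split_inequalities(system)
    res = linprog(
        np.zeros(system.n_foods),
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=system.A_eq if system.A_eq.size else None,
        b_eq=system.b_eq if system.b_eq.size else None,
        bounds=np.column_stack([system.x_lower, system.x_upper]),
        method="highs",
    )
    return res.status == 0


def diagnose_infeasibility(system: ConstraintSystem) -> str:
    """Name the constraint family whose isolated removal restores feasibility.

    One-at-a-time relaxation, not a full irreducible infeasible subsystem:
    bounded effort, actionable output.
    """
    culprits = [f for f in _families(system) if _feasible_point(_relax_family(system, f))]
    if not culprits:
        return "no single constraint family explains the infeasibility"
    return "relaxing any of {" + ", ".join(culprits) + "} restores feasibility"


def _audit(
    x: np.ndarray,
    system: ConstraintSystem,
    universe: FoodUniverse | None,
    objective: float,
    model_kind: str,
    settings: SolverSettings,
) -> DietSolution:
    x = np.asarray(x, dtype=float).copy()
    # snap droplets of solver noise onto the nonnegativity floor
    x[(x < 0) & (x > -settings.feasibility_tol)] = 0.0
    report = verify_solution(x, system, settings.feasibility_tol)
    status = "optimal" if report.feasible else "error"
    if universe is not None:
        totals = solution_totals(x, universe)
    else:
        totals = {"cost": float("nan"), "energy": float("nan"), "ghge": float("nan")}
    return DietSolution(
        x=np.asarray(x, dtype=float),
        status=status,
        objective=objective,
        cost=totals["cost"],
        energy=totals["energy"],
        ghge=totals["ghge"],
        model_kind=model_kind,
        binding=report.binding,
        report=report,
    )


def solve_min_cost(
    system: ConstraintSystem,
    prices: np.ndarray,
    settings: SolverSettings | None = None,
    universe: FoodUniverse | None = None,
) -> DietSolution:
    """Minimum-cost diet: min p.x subject to the assembled linear system."""
    settings = settings or SolverSettings()
    prices = np.asarray(prices, dtype=float)
    if prices.shape != (system.n_foods,):
        raise ValueError("price vector length does not match the system")
    if np.any(prices < 0):
        raise ValueError("prices must be nonnegative")

    a_ub, b_ub = _split_inequalities(system)
    res = linprog(
        prices,
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=system.A_eq if system.A_eq.size else None,
        b_eq=system.b_eq if system.b_eq.size else None,
        bounds=np.column_stack([system.x_lower, system.x_upper]),
        method="highs",
        options={"primal_feasibility_tolerance": settings.optimality_tol},
    )
    if res.status == 2:
        sol = DietSolution(
            x=np.full(system.n_foods, np.nan),
            status="infeasible",
            objective=float("nan"),
            cost=float("nan"),
            energy=float("nan"),
            ghge=float("nan"),
            model_kind="min_cost",
        )
        sol.diagnosis = diagnose_infeasibility(system)
        return sol
    if res.status == 3:
        raise RuntimeError(
            "minimum-cost LP is unbounded; check for a zero-price, zero-energy food"
        )
    if res.status != 0:
        raise RuntimeError(f"LP solver failed: {res.message}")

    objective = float(prices @ res.x)  # recomputed, not taken from the solver
    return _audit(res.x, system, universe, objective, "min_cost", settings)


def _polish_qp(
    system: ConstraintSystem, x: np.ndarray, x0: np.ndarray, settings: SolverSettings
) -> np.ndarray:
    """Refine an iterate to the exact optimum of its active face.

    Interior-point style iterations stop within ~1e-5 of the constrained
    optimum; since the problem is a QP, solving the KKT equality system of
    the detected active set lands on the exact face minimizer in one linear
    solve.  The polished point is kept only if it is feasible and no worse.
    """
    h_diag = 2.0 / x0**2
    n = system.n_foods
    eye = np.eye(n)

    # candidate inequality hyperplanes: (coef, bound, side) with side -1 for a
    # lower bound (multiplier must be <= 0 in our sign convention) and +1 for
    # an upper bound (multiplier >= 0)
    planes: list[tuple[np.ndarray, float, int]] = []
    for k in range(system.A_in.shape[0]):
        if np.isfinite(system.lower[k]):
            planes.append((system.A_in[k], float(system.lower[k]), -1))
        if np.isfinite(system.upper[k]):
            planes.append((system.A_in[k], float(system.upper[k]), +1))
    for i in range(n):
        if np.isfinite(system.x_lower[i]):
            planes.append((eye[i], float(system.x_lower[i]), -1))
        if np.isfinite(system.x_upper[i]):
            planes.append((eye[i], float(system.x_upper[i]), +1))

    def scale(b):
        return max(1.0, abs(b))

    # seed the working set with the constraints the iterate sits on
    working = [
        k for k, (a, b, _) in enumerate(planes)
        if abs(float(a @ x) - b) <= 1e-4 * scale(b)
    ]
    m_eq = system.A_eq.shape[0]
    best = x
    best_obj = deviation_objective(x, x0)

    for _ in range(60):
        a_act = np.vstack([system.A_eq] + [planes[k][0][None, :] for k in working]) \
            if (m_eq or working) else np.zeros((0, n))
        b_act = np.concatenate([system.b_eq, [planes[k][1] for k in working]])
        m = a_act.shape[0]
        kkt = np.block([[np.diag(h_diag), a_act.T], [a_act, np.zeros((m, m))]])
        rhs = np.concatenate([h_diag * x0, b_act])
        sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        x_new, mult = sol[:n], sol[n + m_eq:]

        # most violated non-working constraint, scaled
        worst_k, worst_v = -1, settings.feasibility_tol
        for k, (a, b, side) in enumerate(planes):
            if k in working:
                continue
            v = side * (float(a @ x_new) - b)  # positive = violated
            if v / scale(b) > worst_v:
                worst_k, worst_v = k, v / scale(b)
        if worst_k >= 0:
            working.append(worst_k)
            continue

        report = verify_solution(x_new, system, settings.feasibility_tol)
        obj_new = deviation_objective(x_new, x0)
        if report.feasible and obj_new <= best_obj + 1e-12:
            best, best_obj = x_new, obj_new

        # wrong-signed multiplier: constraint is holding the point back, drop it
        wrong = [
            j for j, k in enumerate(working) if planes[k][2] * mult[j] < -1e-9
        ]
        if not wrong:
            break
        drop = max(wrong, key=lambda j: abs(mult[j]))
        working.pop(drop)
    return best


def deviation_objective(x: np.ndarray, x0: np.ndarray) -> float:
    """Sum of squared relative deviations from the baseline diet."""
    return float(np.sum(((np.asarray(x) - x0) / x0) ** 2))


def solve_min_deviation(
    system: ConstraintSystem,
    x0: np.ndarray,
    settings: SolverSettings | None = None,
    universe: FoodUniverse | None = None,
) -> DietSolution:
    """Minimum-deviation diet: the strictly convex QP described above."""
    settings = settings or SolverSettings()
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (system.n_foods,):
        raise ValueError("baseline vector length does not match the system")
    if np.any(x0 <= 0):
        bad = system.food_ids[int(np.argmin(x0))]
        raise ValueError(
            f"baseline intake must be strictly positive for the minimum-deviation "
            f"model; food {bad!r} has x0 <= 0"
        )

    # the unconstrained minimum of the strictly convex objective is x0 itself;
    # if it is feasible it is the exact global solution and no iteration is needed
    if verify_solution(x0, system, settings.feasibility_tol).feasible:
        return _audit(x0, system, universe, 0.0, "min_deviation", settings)

    w = 1.0 / x0**2

    def fun(x):
        return np.sum(w * (x - x0) ** 2)

    def grad(x):
        return 2.0 * w * (x - x0)

    hess = np.diag(2.0 * w)

    cons = []
    if system.A_eq.size:
        cons.append(LinearConstraint(system.A_eq, system.b_eq, system.b_eq))
    if system.A_in.size:
        cons.append(LinearConstraint(system.A_in, system.lower, system.upper))
    bounds = Bounds(system.x_lower, system.x_upper)
    start = np.clip(x0, system.x_lower, system.x_upper)

    import warnings

    if settings.qp_backend == "trust-constr":
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Singular Jacobian matrix")
            res = minimize(
                fun,
                start,
                jac=grad,
                hess=lambda x: hess,
                method="trust-constr",
                constraints=cons,
                bounds=bounds,
                options={
                    "gtol": settings.optimality_tol,
                    "xtol": 1e-12,
                    "maxiter": max(settings.max_iter, 200),
                },
            )
    elif settings.qp_backend == "slsqp":
        slsqp_cons = []
        if system.A_eq.size:
            slsqp_cons.append(
                {
                    "type": "eq",
                    "fun": lambda x: system.A_eq @ x - system.b_eq,
                    "jac": lambda x: system.A_eq,
                }
            )
        finite_lo = np.isfinite(system.lower)
        finite_up = np.isfinite(system.upper)
        if finite_lo.any():
            a_lo, b_lo = system.A_in[finite_lo], system.lower[finite_lo]
            slsqp_cons.append(
                {"type": "ineq", "fun": lambda x: a_lo @ x - b_lo, "jac": lambda x: a_lo}
            )
        if finite_up.any():
            a_up, b_up = system.A_in[finite_up], system.upper[finite_up]
            slsqp_cons.append(
                {"type": "ineq", "fun": lambda x: b_up - a_up @ x, "jac": lambda x: -a_up}
            )
        res = minimize(
            fun,
            start,
            jac=grad,
            method="SLSQP",
            constraints=slsqp_cons,
            bounds=bounds,
            options={"maxiter": max(settings.max_iter, 500), "ftol": settings.optimality_tol},
        )
    else:
        raise ValueError(f"unknown QP backend {settings.qp_backend!r}")

    x_hat = _polish_qp(system, res.x, x0, settings)
    objective = deviation_objective(x_hat, x0)
    sol = _audit(x_hat, system, universe, objective, "min_deviation", settings)
    if sol.status == "error":
        # distinguish a genuinely infeasible system from solver failure
        if not _feasible_point(system):
            sol.status = "infeasible"
            sol.diagnosis = diagnose_infeasibility(system)
    return sol


def run_model(
    universe: FoodUniverse,
    group: PopulationGroup,
    scenario: Scenario,
    model_kind: str,
    settings: SolverSettings | None = None,
    config: BuilderConfig | None = None,
) -> DietSolution:
    """Build the constraint system, solve, and return the audited solution."""
    settings = settings or SolverSettings()
    system = build(universe, group, scenario, model_kind, config)
    if model_kind == "min_cost":
        return solve_min_cost(system, universe.prices, settings, universe)
    return solve_min_deviation(system, group.x0, settings, universe)
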