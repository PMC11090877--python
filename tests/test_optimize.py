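import numpy as np
import pytest

from dietopt import (
    HEALTH_GHGE_MINUS50,
    HEALTH_ONLY,
    ConstraintSystem,
    SolverSettings,
    run_model,
    solve_min_cost,
    solve_min_deviation,
)
from dietopt.optimize import deviation_objective

from oracles import lp_vertex_enumeration, qp_active_set_enumeration, random_feasible_system


class TestMinCost:
    def test_single_food_forced_by_energy_equality(self):
        system = ConstraintSystem(["only"])
        system.add_equality(np.array([10.0]), 1000.0, "energy")
        sol = solve_min_cost(system, np.array([0.001]))
        assert sol.status == "optimal"
        assert sol.x == pytest.approx([100.0])
        assert sol.objective == pytest.approx(0.10)

    def test_objective_matches_vertex_enumeration(self):
        """HiGHS must agree with brute-force vertex enumeration on 100
        random small instances."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(2, 4))
            system, _ = random_feasible_system(rng, n, int(rng.integers(0, 3)))
            c = rng.uniform(0.1, 2.0, n)
            brute, _ = lp_vertex_enumeration(system, c)
            sol = solve_min_cost(system, c)
            assert sol.status == "optimal"
            assert sol.objective == pytest.approx(brute, rel=1e-6, abs=1e-9)

    def test_optimal_cost_below_baseline_when_baseline_feasible(self, default_dataset):
        universe, group = default_dataset
        sol = run_model(universe, group, HEALTH_ONLY, "min_cost")
        assert sol.status == "optimal"
        assert sol.cost <= group.baseline_cost(universe) + 1e-9

    def test_price_scaling_scales_objective_not_argmin(self):
        rng = np.random.default_rng(5)
        system, _ = random_feasible_system(rng, 3, 1)
        c = rng.uniform(0.1, 1.0, 3)
        a = solve_min_cost(system, c)
        b = solve_min_cost(system, 7.0 * c)
        assert b.objective == pytest.approx(7.0 * a.objective, rel=1e-9)
        assert b.x == pytest.approx(a.x, abs=1e-7)

    def test_infeasible_reports_culprit_family(self):
        system = ConstraintSystem(["a", "b"])
        system.add_equality(np.array([1.0, 1.0]), 100.0, "energy")
        system.add_inequality(np.array([1.0, 1.0]), 200.0, np.inf, "nutrient:x")
        sol = solve_min_cost(system, np.array([1.0, 1.0]))
        assert sol.status == "infeasible"
        assert "nutrient" in sol.diagnosis or "energy" in sol.diagnosis


class TestMinDeviation:
    def test_feasible_baseline_is_returned_exactly(self):
        system = ConstraintSystem(["a", "b"])
        x0 = np.array([100.0, 100.0])
        system.add_equality(np.array([1.0, 1.0]), 200.0, "energy")
        sol = solve_min_deviation(system, x0)
        assert sol.status == "optimal"
        assert sol.objective == 0.0
        assert np.array_equal(sol.x, x0)

    def test_closed_form_two_food_equality(self):
        """Equal weights and a +10% energy requirement move both foods
        +10%: objective 2 * 0.1^2 = 0.02 by the Lagrange solution."""
        system = ConstraintSystem(["a", "b"])
        system.add_equality(np.array([1.0, 1.0]), 220.0, "energy")
        sol = solve_min_deviation(system, np.array([100.0, 100.0]))
        assert sol.status == "optimal"
        assert sol.x == pytest.approx([110.0, 110.0], abs=1e-6)
        assert sol.objective == pytest.approx(0.02, abs=1e-8)

    def test_objective_matches_kkt_enumeration(self):
        """Iterative QP must agree with exact active-set enumeration on 50
        random small instances."""
        rng = np.random.default_rng(321)
        for _ in range(50):
            n = int(rng.integers(2, 7))
            system, x_feas = random_feasible_system(rng, n, int(rng.integers(0, 4)))
            x0 = x_feas * rng.uniform(0.7, 1.4, n)  # baseline off the feasible point
            brute, _ = qp_active_set_enumeration(system, x0)
            sol = solve_min_deviation(system, x0)
            assert sol.status == "optimal"
            assert sol.objective == pytest.approx(brute, rel=1e-6, abs=1e-6)

    def test_nonpositive_baseline_names_the_food(self):
        system = ConstraintSystem(["a", "bad"])
        with pytest.raises(ValueError, match="bad"):
            solve_min_deviation(system, np.array([1.0, 0.0]))

    def test_backends_agree_on_random_instances(self):
        """trust-constr and SLSQP find the same unique optimum."""
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(2, 7))
            system, x_feas = random_feasible_system(rng, n, int(rng.integers(0, 3)))
            x0 = x_feas * rng.uniform(0.7, 1.4, n)
            a = solve_min_deviation(system, x0, SolverSettings(qp_backend="trust-constr"))
            b = solve_min_deviation(system, x0, SolverSettings(qp_backend="slsqp"))
            assert a.status == b.status == "optimal"
            assert a.x == pytest.approx(b.x, abs=1e-5)

    def test_objective_recomputed_from_x(self):
        system = ConstraintSystem(["a", "b"])
        system.add_equality(np.array([1.0, 2.0]), 500.0, "energy")
        x0 = np.array([80.0, 150.0])
        sol = solve_min_deviation(system, x0)
        assert sol.objective == pytest.approx(deviation_objective(sol.x, x0), rel=1e-12)


class TestRunModel:
    def test_cap_binds_in_minus50_min_deviation(self, stress_dataset):
        universe, group = stress_dataset
        sol = run_model(universe, group, HEALTH_GHGE_MINUS50, "min_deviation")
        assert sol.status == "optimal"
        assert "ghge" in sol.binding
        assert sol.ghge * 1000 == pytest.approx(0.5 * group.baseline_ghge(universe), rel=1e-6)

    def test_cap_slack_for_min_cost_on_defaults(self, default_dataset):
        """The cheapest nutritionally adequate diet is already low-emission,
        so the cap is not binding."""
        universe, group = default_dataset
        sol = run_model(universe, group, HEALTH_GHGE_MINUS50, "min_cost")
        assert sol.status == "optimal"
        assert "ghge" not in sol.binding
        assert sol.ghge * 1000 < 0.5 * group.baseline_ghge(universe)

    def test_permutation_invariance_of_objectives(self, stress_dataset):
        from dietopt import FoodUniverse, PopulationGroup

        universe, group = stress_dataset
        rng = np.random.default_rng(17)
        perm = rng.permutation(universe.n_foods)
        uni_p = FoodUniverse(
            [universe.foods[i] for i in perm], universe.nutrients, universe.bounds,
            universe.milk_per_beef,
        )
        grp_p = PopulationGroup(
            group.sex, group.label, group.x0[perm], group.p10[perm], group.p90[perm]
        )
        for model in ("min_cost", "min_deviation"):
            a = run_model(universe, group, HEALTH_GHGE_MINUS50, model)
            b = run_model(uni_p, grp_p, HEALTH_GHGE_MINUS50, model)
            assert b.objective == pytest.approx(a.objective, abs=1e-6, rel=1e-6)
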