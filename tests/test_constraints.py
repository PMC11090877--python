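import numpy as np
import pytest

from dietopt import (
    HEALTH_GHGE_MINUS33,
    HEALTH_GHGE_MINUS50,
    HEALTH_ONLY,
    BuilderConfig,
    NutrientBounds,
    build,
    verify_solution,
)
from dietopt.constraints import (
    dairy_beef_row,
    energy_equality,
    ghge_cap,
    habit_rows,
    nutrient_rows,
)


class TestEnergyEquality:
    def test_baseline_satisfies_exactly(self, tiny_universe, tiny_group):
        coef, rhs = energy_equality(tiny_universe, tiny_group)
        assert float(coef @ tiny_group.x0) == pytest.approx(rhs, rel=1e-15)

    def test_synthetic_female_default_rhs(self, default_dataset):
        universe, group = default_dataset
        _, rhs = energy_equality(universe, group)
        assert rhs == pytest.approx(7311.0)

    def test_invariant_under_compensating_rescale(self, tiny_universe, tiny_group):
        """Doubling densities while halving intakes leaves E0 unchanged."""
        from dataclasses import replace

        from dietopt import FoodUniverse, PopulationGroup

        foods2 = [replace(f, energy_kj_per_g=2 * f.energy_kj_per_g) for f in tiny_universe.foods]
        uni2 = FoodUniverse(foods2, tiny_universe.nutrients, tiny_universe.bounds)
        grp2 = PopulationGroup(
            "female", "all", tiny_group.x0 / 2, tiny_group.p10 / 2, tiny_group.p90 / 2
        )
        _, rhs1 = energy_equality(tiny_universe, tiny_group)
        _, rhs2 = energy_equality(uni2, grp2)
        assert rhs2 == pytest.approx(rhs1, rel=1e-12)


class TestNutrientRows:
    def _row(self, rows, nid):
        (hit,) = [r for r in rows if r[3] == f"nutrient:{nid}"]
        return hit

    def test_upper_only_bound_gets_minus_inf_floor(self, tiny_universe, tiny_group):
        rows = nutrient_rows(tiny_universe, tiny_group)
        _, lo, hi, _ = self._row(rows, "fiber")
        assert lo == -np.inf and hi == pytest.approx(50.0)

    def test_amino_acid_safety_margin(self, tiny_universe, tiny_group):
        """A 1.0 g/d lysine floor becomes 1.24 g/d after the safety margin."""
        rows = nutrient_rows(tiny_universe, tiny_group)
        _, lo, _, _ = self._row(rows, "lysine")
        assert lo == pytest.approx(1.24)

    def test_pct_energy_linearization(self, tiny_universe, tiny_group):
        """%E bounds become kJ rows: coef 37*a_fat, rhs L/100 * E0."""
        rows = nutrient_rows(tiny_universe, tiny_group)
        coef, lo, hi, _ = self._row(rows, "fat")
        e0 = tiny_group.baseline_energy(tiny_universe)
        assert coef == pytest.approx(37.0 * tiny_universe.nutrient_row("fat"))
        assert lo == pytest.approx(0.20 * e0)
        assert hi == pytest.approx(0.40 * e0)

    def test_pct_energy_without_conversion_factor_errors(self, tiny_universe, tiny_group):
        cfg = BuilderConfig(energy_conversion={"protein": 17.0})
        with pytest.raises(ValueError, match="conversion"):
            nutrient_rows(tiny_universe, tiny_group, cfg)

    def test_female_iron_floor_is_baseline_intake(self, tiny_universe, tiny_group):
        rows = nutrient_rows(tiny_universe, tiny_group)
        coef, lo, _, _ = self._row(rows, "iron")
        assert lo == pytest.approx(float(tiny_universe.nutrient_row("iron") @ tiny_group.x0))
        # the rule never makes the baseline iron-infeasible
        assert float(coef @ tiny_group.x0) >= lo - 1e-12

    def test_iron_rule_off_for_males(self, tiny_universe, tiny_group):
        from dietopt import PopulationGroup

        male = PopulationGroup("male", "all", tiny_group.x0, tiny_group.p10, tiny_group.p90)
        bounds = [NutrientBounds(b.nutrient_id, "male", b.lower, b.upper) for b in tiny_universe.bounds]
        tiny_universe.bounds = bounds
        rows = nutrient_rows(tiny_universe, male)
        _, lo, _, _ = self._row(rows, "iron")
        assert lo == pytest.approx(5.0)


class TestGhgeCap:
    def test_half_of_baseline(self, tiny_universe, tiny_group):
        coef, rhs = ghge_cap(tiny_universe, tiny_group, HEALTH_GHGE_MINUS50)
        assert rhs == pytest.approx(0.5 * tiny_group.baseline_ghge(tiny_universe))
        assert coef == pytest.approx(tiny_universe.ghge)

    def test_health_only_has_no_row(self, tiny_universe, tiny_group):
        assert ghge_cap(tiny_universe, tiny_group, HEALTH_ONLY) is None

    def test_unit_fraction_leaves_zero_margin_at_baseline(self, tiny_universe, tiny_group):
        from dietopt import Scenario

        coef, rhs = ghge_cap(tiny_universe, tiny_group, Scenario("theta1", 1.0))
        assert float(coef @ tiny_group.x0) == pytest.approx(rhs, rel=1e-12)


class TestDairyBeef:
    def test_exact_jointness_is_binding(self, tiny_universe):
        """33.9 g milk-equivalent dairy against 1 g of pure beef: zero slack."""
        row = dairy_beef_row(tiny_universe)
        x = np.array([0.0, 1.0, 33.9, 0.0])  # bread, beef, milk, carrot
        assert float(row @ x) == pytest.approx(0.0, abs=1e-12)

    def test_all_plant_diet_satisfied(self, tiny_universe):
        row = dairy_beef_row(tiny_universe)
        x = np.array([100.0, 0.0, 0.0, 50.0])
        assert float(row @ x) == pytest.approx(0.0, abs=1e-12)

    def test_sign_matches_direct_evaluation(self, tiny_universe):
        rng = np.random.default_rng(2)
        row = dairy_beef_row(tiny_universe)
        rho = tiny_universe.milk_per_beef
        for _ in range(50):
            x = rng.uniform(0, 100, 4)
            direct = rho * float(tiny_universe.beef_fraction @ x) - float(
                tiny_universe.raw_milk_equiv @ x
            )
            assert np.sign(row @ x) == np.sign(direct)
            assert float(row @ x) == pytest.approx(direct, rel=1e-12)

    def test_dairy_without_beef_is_structural_error(self, tiny_universe):
        from dietopt import FoodUniverse

        foods = [f for f in tiny_universe.foods if f.id != "beef"]
        uni = FoodUniverse(foods, tiny_universe.nutrients)
        with pytest.raises(ValueError, match="structurally infeasible"):
            dairy_beef_row(uni)


class TestBuildAndHabit:
    def test_degenerate_habit_interval_pins_the_food(self, tiny_group):
        tiny_group.p10[2] = tiny_group.p90[2] = 123.0
        lo, hi = habit_rows(tiny_group)
        assert lo[2] == hi[2] == 123.0

    def test_min_cost_model_has_nonnegativity_only(self, tiny_universe, tiny_group):
        system = build(tiny_universe, tiny_group, HEALTH_ONLY, "min_cost")
        assert np.all(system.x_lower == 0)
        assert np.all(np.isinf(system.x_upper))

    def test_row_census(self, tiny_universe, tiny_group):
        """1 energy equality + one row per bounded nutrient + [cap] + dairy-beef."""
        for scenario, extra in ((HEALTH_ONLY, 0), (HEALTH_GHGE_MINUS50, 1)):
            system = build(tiny_universe, tiny_group, scenario, "min_deviation")
            assert system.eq_labels == ["energy"]
            assert len(system.in_labels) == 4 + extra + 1
            assert ("ghge" in system.in_labels) == bool(extra)
            assert system.in_labels[-1] == "dairy_beef"

    def test_baseline_feasible_in_default_synthetic_system(self, default_dataset):
        universe, group = default_dataset
        system = build(universe, group, HEALTH_ONLY, "min_deviation")
        assert verify_solution(group.x0, system).feasible

    def test_tighter_cap_shrinks_feasible_set(self, default_dataset):
        """Any diet feasible at theta=1/2 is feasible at theta=2/3."""
        universe, group = default_dataset
        from dietopt import run_model

        s50 = build(universe, group, HEALTH_GHGE_MINUS50, "min_deviation")
        s33 = build(universe, group, HEALTH_GHGE_MINUS33, "min_deviation")
        sol = run_model(universe, group, HEALTH_GHGE_MINUS50, "min_deviation")
        assert sol.status == "optimal"
        assert verify_solution(sol.x, s50).feasible
        assert verify_solution(sol.x, s33).feasible
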