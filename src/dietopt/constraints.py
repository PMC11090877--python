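"""Assembly of the linear constraint system for both diet models.

The full system for a (universe, group, scenario, model) combination is:

* one isocaloric equality  sum_i e_i x_i = E0
* one two-sided row per bounded nutrient  L_j <= sum_i a_ji x_i <= U_j
  (``%E`` bounds linearized against the fixed energy level E0, amino-acid
  lower bounds inflated by a safety margin, and the female iron floor pinned
  to the baseline iron intake)
* an optional GHGE cap  sum_i g_i x_i <= theta * G0
* one dairy-beef jointness row  rho * sum_i b_i x_i - sum_i r_i x_i >= 0
* variable bounds: the food-habit box [p10, p90] for the minimum-deviation
  model, plain nonnegativity for the minimum-cost model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConstraintSystem, FoodUniverse, PopulationGroup, Scenario

MODEL_KINDS = ("min_cost", "min_deviation")

#: kJ released per gram of each energy-yielding macronutrient, used to
#: linearize %E bounds under the isocaloric equality
DEFAULT_ENERGY_CONVERSION = {
    "fat": 37.0,
    "protein": 17.0,
    "carbohydrate": 17.0,
    "alcohol": 29.0,
}


@dataclass
class BuilderConfig:
    """Tunable parameters of constraint assembly."""

    energy_conversion: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENERGY_CONVERSION)
    )
    amino_safety_multiplier: float = 1.24
    iron_rule_female: bool = True
    iron_nutrient_id: str = "iron"
    include_habit_bounds: bool | None = None  # None: decided by model kind
    milk_per_beef: float | None = None  # None: use the universe's value

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.energy_conversion.values()):
            raise ValueError("energy conversion factors must be positive")
        if self.amino_safety_multiplier < 1.0:
            raise ValueError("amino safety multiplier must be >= 1")


def energy_equality(universe: FoodUniverse, group: PopulationGroup):
    """Isocaloric row: total energy fixed at the observed baseline level E0."""
    e0 = group.baseline_energy(universe)
    if e0 <= 0:
        raise ValueError("baseline energy must be positive")
    return universe.energy_density.copy(), e0


def nutrient_rows(
    universe: FoodUniverse,
    group: PopulationGroup,
    config: BuilderConfig | None = None,
) -> list[tuple[np.ndarray, float, float, str]]:
    """Two-sided rows (coef, lower, upper, label), one per bounded nutrient.

    Nutrients bounded in %E are converted to kJ rows: a bound of L percent of
    energy becomes ``sum_i (conv_j * a_ji) x_i >= L/100 * E0``, which is
    linear because total energy is fixed by the isocaloric equality.
    """
    config = config or BuilderConfig()
    a = universe.nutrient_matrix()
    e0 = group.baseline_energy(universe)
    rows = []
    for b in universe.bounds_for_sex(group.sex):
        nut = universe.nutrient(b.nutrient_id)
        j = universe.nutrient_ids.index(b.nutrient_id)
        coef = a[j].copy()
        lower = -np.inf if b.lower is None else float(b.lower)
        upper = np.inf if b.upper is None else float(b.upper)

        if nut.unit == "%E":
            try:
                conv = config.energy_conversion[nut.id]
            except KeyError:
                raise ValueError(
                    f"%E nutrient {nut.id!r} has no energy conversion factor"
                ) from None
            coef = conv * coef
            if np.isfinite(lower):
                lower = lower / 100.0 * e0
            if np.isfinite(upper):
                upper = upper / 100.0 * e0

        if nut.kind == "amino_acid" and np.isfinite(lower):
            lower = config.amino_safety_multiplier * lower

        if (
            config.iron_rule_female
            and group.sex == "female"
            and nut.id == config.iron_nutrient_id
            and np.isfinite(lower)
        ):
            # iron floor at the concentration of the current (isocaloric) diet
            lower = float(coef @ group.x0)

        rows.append((coef, lower, upper, f"nutrient:{nut.id}"))
    return rows


def ghge_cap(universe: FoodUniverse, group: PopulationGroup, scenario: Scenario):
    """GHGE row ``sum_i g_i x_i <= theta * G0``, or None for health-only."""
    if scenario.ghge_fraction is None:
        return None
    g0 = group.baseline_ghge(universe)
    if g0 <= 0:
        raise ValueError("baseline GHGE must be positive")
    return universe.ghge.copy(), scenario.ghge_fraction * g0


def dairy_beef_row(universe: FoodUniverse, config: BuilderConfig | None = None):
    """Food-system jointness row ``rho * sum b_i x_i - sum r_i x_i >= 0``.

    Consuming dairy (raw-milk equivalents r_i) implies the co-production of
    beef carcass at the yield rho; the diet must absorb at least that much
    beef-carcass mass via the beef-bearing foods (fractions b_i).
    """
    config = config or BuilderConfig()
    rho = config.milk_per_beef if config.milk_per_beef is not None else universe.milk_per_beef
    b = universe.beef_fraction
    r = universe.raw_milk_equiv
    if np.any(r > 0) and not np.any(b > 0):
        raise ValueError(
            "universe contains dairy but no beef-bearing food: "
            "dairy-containing diets are structurally infeasible"
        )
    return rho * b - r


def habit_rows(group: PopulationGroup) -> tuple[np.ndarray, np.ndarray]:
    """Food-habit box bounds p10 <= x <= p90 (minimum-deviation model)."""
    if np.any(group.p10 > group.p90):
        raise ValueError("p10 exceeds p90 for some food")
    return group.p10.copy(), group.p90.copy()


def build(
    universe: FoodUniverse,
    group: PopulationGroup,
    scenario: Scenario,
    model_kind: str,
    config: BuilderConfig | None = None,
) -> ConstraintSystem:
    """Assemble the full constraint system for one model run."""
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    config = config or BuilderConfig()

    system = ConstraintSystem(universe.food_ids)

    coef, e0 = energy_equality(universe, group)
    system.add_equality(coef, e0, "energy")

    for coef, lower, upper, label in nutrient_rows(universe, group, config):
        system.add_inequality(coef, lower, upper, label)

    cap = ghge_cap(universe, group, scenario)
    if cap is not None:
        system.add_inequality(cap[0], -np.inf, cap[1], "ghge")

    system.add_inequality(dairy_beef_row(universe, config), 0.0, np.inf, "dairy_beef")

    include_habit = config.include_habit_bounds
    if include_habit is None:
        include_habit = model_kind == "min_deviation"
    if include_habit:
        lo, hi = habit_rows(group)
        system.set_variable_bounds(lo, hi)

    return system
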