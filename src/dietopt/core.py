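"""Core domain types for diet-optimization models.

Unit conventions used throughout the package:

* food quantities: g per capita per day
* energy density: kJ per g of food (diet energy reported in kJ/cap/d)
* price: EUR per g of food (diet cost reported in EUR/cap/d)
* greenhouse-gas emission (GHGE) intensity: g CO2e per g of food
  (diet GHGE reported in kg CO2e/cap/d)
* nutrient densities: amount of the nutrient (in its own unit) per g of food

The food universe is a flat list of food categories (74 in the default
application), each mapped to exactly one of 16 main food categories used for
reporting.  The dairy-beef jointness of the food system is described by a
beef-carcass fraction ``b_i`` per food and a raw-milk equivalent ``r_i``
(g raw milk needed per g of food, positive only for dairy), tied together by
the yield ``milk_per_beef``: grams of raw milk co-produced with one gram of
beef carcass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MAIN_CATEGORIES = (
    "Alcohol",
    "Beverages",
    "Cereals",
    "Diet products",
    "Eggs",
    "Fats",
    "Fish",
    "Flavoring",
    "Fruits",
    "Ingredients",
    "Legumes and nuts",
    "Meat",
    "Dairy",
    "Potatoes",
    "Sugar",
    "Vegetables",
)

NUTRIENT_UNITS = ("g/d", "mg/d", "ug/d", "%E")
NUTRIENT_KINDS = ("macronutrient", "vitamin", "mineral", "amino_acid")

#: default raw-milk yield per gram of beef carcass in a dairy-dominated chain
DEFAULT_MILK_PER_BEEF = 33.9

#: feasibility / binding tolerance on constraint rows (double-precision LP/QP)
FEASIBILITY_TOL = 1e-6


@dataclass(frozen=True)
class NutrientDef:
    """One nutrient tracked by the model."""

    id: str
    name: str
    unit: str
    kind: str

    def __post_init__(self) -> None:
        if self.unit not in NUTRIENT_UNITS:
            raise ValueError(f"unknown nutrient unit {self.unit!r} for {self.id}")
        if self.kind not in NUTRIENT_KINDS:
            raise ValueError(f"unknown nutrient kind {self.kind!r} for {self.id}")


@dataclass(frozen=True)
class NutrientBounds:
    """Lower/upper bound on the daily intake of one nutrient for one sex.

    ``lower``/``upper`` are expressed in the nutrient's own unit (``%E``
    bounds as percent of dietary energy).  At least one must be present.
    """

    nutrient_id: str
    sex: str
    lower: float | None = None
    upper: float | None = None
    source: str = "recommended"

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise ValueError(f"bound for {self.nutrient_id}: lower and upper both absent")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError(f"bound for {self.nutrient_id}: lower > upper")


@dataclass(frozen=True)
class FoodCategory:
    """One food category of the (74-level) universe."""

    id: str
    name: str
    main_category: str
    energy_kj_per_g: float
    price_eur_per_g: float
    ghge_g_per_g: float
    nutrient_density: Mapping[str, float] = field(default_factory=dict)
    beef_fraction: float = 0.0
    raw_milk_equiv: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beef_fraction <= 1.0:
            raise ValueError(f"{self.id}: beef_fraction must lie in [0, 1]")
        for label, v in (
            ("energy_kj_per_g", self.energy_kj_per_g),
            ("price_eur_per_g", self.price_eur_per_g),
            ("ghge_g_per_g", self.ghge_g_per_g),
            ("raw_milk_equiv", self.raw_milk_equiv),
        ):
            if v < 0:
                raise ValueError(f"{self.id}: {label} must be nonnegative")


class FoodUniverse:
    """Ordered food categories plus nutrient definitions and intake bounds."""

    def __init__(
        self,
        foods: Sequence[FoodCategory],
        nutrients: Sequence[NutrientDef],
        bounds: Sequence[NutrientBounds] = (),
        milk_per_beef: float = DEFAULT_MILK_PER_BEEF,
    ) -> None:
        self.foods = list(foods)
        self.nutrients = list(nutrients)
        self.bounds = list(bounds)
        self.milk_per_beef = float(milk_per_beef)

        ids = [f.id for f in self.foods]
        if len(set(ids)) != len(ids):
            raise ValueError("food ids are not unique")
        nids = [n.id for n in self.nutrients]
        if len(set(nids)) != len(nids):
            raise ValueError("nutrient ids are not unique")
        known = set(nids)
        for b in self.bounds:
            if b.nutrient_id not in known:
                raise ValueError(f"bound references unknown nutrient {b.nutrient_id!r}")

        self.food_ids = ids
        self.nutrient_ids = nids
        self._food_index = {fid: i for i, fid in enumerate(ids)}
        self._nutrient_index = {nid: j for j, nid in enumerate(nids)}

    # -- vector/matrix views -------------------------------------------------
    @property
    def n_foods(self) -> int:
        return len(self.foods)

    @property
    def energy_density(self) -> np.ndarray:
        return np.array([f.energy_kj_per_g for f in self.foods])

    @property
    def prices(self) -> np.ndarray:
        return np.array([f.price_eur_per_g for f in self.foods])

    @property
    def ghge(self) -> np.ndarray:
        return np.array([f.ghge_g_per_g for f in self.foods])

    @property
    def beef_fraction(self) -> np.ndarray:
        return np.array([f.beef_fraction for f in self.foods])

    @property
    def raw_milk_equiv(self) -> np.ndarray:
        return np.array([f.raw_milk_equiv for f in self.foods])

    @property
    def main_category(self) -> list[str]:
        return [f.main_category for f in self.foods]

    def nutrient_matrix(self) -> np.ndarray:
        """Densities ``a[j, i]``: amount of nutrient j per g of food i."""
        a = np.zeros((len(self.nutrients), self.n_foods))
        for i, f in enumerate(self.foods):
            for nid, v in f.nutrient_density.items():
                a[self._nutrient_index[nid], i] = v
        return a

    def nutrient_row(self, nutrient_id: str) -> np.ndarray:
        j = self._nutrient_index[nutrient_id]
        return self.nutrient_matrix()[j]

    def food_index(self, food_id: str) -> int:
        return self._food_index[food_id]

    def nutrient(self, nutrient_id: str) -> NutrientDef:
        return self.nutrients[self._nutrient_index[nutrient_id]]

    def bounds_for_sex(self, sex: str) -> list[NutrientBounds]:
        return [b for b in self.bounds if b.sex == sex]


@dataclass
class PopulationGroup:
    """A population stratum with its baseline diet and habit percentiles.

    ``x0`` is the observed mean intake vector (g/cap/d), ``p10``/``p90`` the
    10th/90th centiles of the per-person consumption distribution used as
    food-habit bounds in the minimum-deviation model.
    """

    sex: str
    label: str
    x0: np.ndarray
    p10: np.ndarray
    p90: np.ndarray

    GROUP_LABELS = ("all", "edu_low", "edu_medium", "edu_high", "inc_q1", "inc_q3", "inc_q5")

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=float)
        self.p10 = np.asarray(self.p10, dtype=float)
        self.p90 = np.asarray(self.p90, dtype=float)
        if not (self.x0.shape == self.p10.shape == self.p90.shape):
            raise ValueError("x0, p10, p90 must have equal length")
        if np.any(self.x0 < 0) or np.any(self.p10 < 0):
            raise ValueError("intakes must be nonnegative")
        if np.any(self.p10 > self.p90):
            raise ValueError("p10 must not exceed p90")

    def baseline_energy(self, universe: FoodUniverse) -> float:
        """E0 = sum_i e_i x0_i, in kJ/cap/d."""
        return float(universe.energy_density @ self.x0)

    def baseline_ghge(self, universe: FoodUniverse) -> float:
        """G0 in g CO2e/cap/d."""
        return float(universe.ghge @ self.x0)

    def baseline_cost(self, universe: FoodUniverse) -> float:
        """C0 in EUR/cap/d."""
        return float(universe.prices @ self.x0)


@dataclass(frozen=True)
class Scenario:
    """A GHGE policy scenario: no cap, or a cap at a fraction of baseline."""

    name: str
    ghge_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.ghge_fraction is not None and not 0.0 < self.ghge_fraction <= 1.0:
            raise ValueError("ghge_fraction must lie in (0, 1]")


HEALTH_ONLY = Scenario("health_only", None)
HEALTH_GHGE_MINUS33 = Scenario("health_ghge_minus33", 2.0 / 3.0)
HEALTH_GHGE_MINUS50 = Scenario("health_ghge_minus50", 0.5)
SCENARIOS = {s.name: s for s in (HEALTH_ONLY, HEALTH_GHGE_MINUS33, HEALTH_GHGE_MINUS50)}


class ConstraintSystem:
    """Linear equalities, two-sided inequalities, and variable bounds.

    Every row carries a label of the form ``family`` or ``family:<id>`` with
    family in {energy, nutrient, ghge, dairy_beef, habit}.
    """

    def __init__(self, food_ids: Sequence[str]):
        self.food_ids = list(food_ids)
        n = len(self.food_ids)
        self.A_eq = np.zeros((0, n))
        self.b_eq = np.zeros(0)
        self.eq_labels: list[str] = []
        self.A_in = np.zeros((0, n))
        self.lower = np.zeros(0)
        self.upper = np.zeros(0)
        self.in_labels: list[str] = []
        self.x_lower = np.zeros(n)
        self.x_upper = np.full(n, np.inf)

    @property
    def n_foods(self) -> int:
        return len(self.food_ids)

    def add_equality(self, coef: np.ndarray, rhs: float, label: str) -> None:
        coef = np.asarray(coef, dtype=float)
        if coef.shape != (self.n_foods,):
            raise ValueError(f"row {label!r}: coefficient length mismatch")
        self.A_eq = np.vstack([self.A_eq, coef])
        self.b_eq = np.append(self.b_eq, float(rhs))
        self.eq_labels.append(label)

    def add_inequality(self, coef: np.ndarray, lower: float, upper: float, label: str) -> None:
        coef = np.asarray(coef, dtype=float)
        if coef.shape != (self.n_foods,):
            raise ValueError(f"row {label!r}: coefficient length mismatch")
        if lower > upper:
            raise ValueError(f"row {label!r}: lower > upper")
        self.A_in = np.vstack([self.A_in, coef])
        self.lower = np.append(self.lower, float(lower))
        self.upper = np.append(self.upper, float(upper))
        self.in_labels.append(label)

    def set_variable_bounds(self, lower: np.ndarray, upper: np.ndarray) -> None:
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        if lower.shape != (self.n_foods,) or upper.shape != (self.n_foods,):
            raise ValueError("variable bound length mismatch")
        if np.any(lower > upper):
            raise ValueError("variable lower bound exceeds upper bound")
        self.x_lower = lower
        self.x_upper = upper

    def row(self, label: str) -> tuple[np.ndarray, float, float]:
        """Coefficients and (lower, upper) of the first row with this label."""
        if label in self.eq_labels:
            k = self.eq_labels.index(label)
            return self.A_eq[k], self.b_eq[k], self.b_eq[k]
        if label in self.in_labels:
            k = self.in_labels.index(label)
            return self.A_in[k], self.lower[k], self.upper[k]
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {
            "food_ids": self.food_ids,
            "equalities": [
                {"label": lab, "coef": self.A_eq[k].tolist(), "rhs": float(self.b_eq[k])}
                for k, lab in enumerate(self.eq_labels)
            ],
            "inequalities": [
                {
                    "label": lab,
                    "coef": self.A_in[k].tolist(),
                    "lower": float(self.lower[k]),
                    "upper": float(self.upper[k]),
                }
                for k, lab in enumerate(self.in_labels)
            ],
            "x_lower": self.x_lower.tolist(),
            "x_upper": np.where(np.isinf(self.x_upper), None, self.x_upper).tolist(),
        }


@dataclass
class RowSlack:
    label: str
    value: float
    lower: float
    upper: float

    @property
    def slack(self) -> float:
        """Distance to the nearest violated side; negative means violated."""
        return min(self.value - self.lower, self.upper - self.value)


@dataclass
class ViolationReport:
    rows: list[RowSlack]
    worst_violation: float
    feasible: bool
    binding: list[str]

    def to_dict(self) -> dict:
        return {
            "feasible": self.feasible,
            "worst_violation": self.worst_violation,
            "binding": self.binding,
            "rows": [asdict(r) | {"slack": r.slack} for r in self.rows],
        }


@dataclass
class DietSolution:
    """An audited solution diet: quantities plus recomputed totals."""

    x: np.ndarray
    status: str  # optimal | infeasible | error
    objective: float
    cost: float
    energy: float
    ghge: float  # kg CO2e/cap/d
    model_kind: str
    binding: list[str] = field(default_factory=list)
    report: ViolationReport | None = None
    diagnosis: str | None = None

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "model_kind": self.model_kind,
            "objective": self.objective,
            "cost": self.cost,
            "energy": self.energy,
            "ghge": self.ghge,
            "binding": self.binding,
            "diagnosis": self.diagnosis,
            "x": np.asarray(self.x, dtype=float).tolist(),
        }


def solution_totals(x: np.ndarray, universe: FoodUniverse) -> dict[str, float]:
    """Cost (EUR), energy (kJ) and GHGE (kg CO2e) per capita per day."""
    x = np.asarray(x, dtype=float)
    return {
        "quantity": float(x.sum()),
        "cost": float(universe.prices @ x),
        "energy": float(universe.energy_density @ x),
        "ghge": float(universe.ghge @ x) / 1000.0,
    }


def verify_solution(
    x: np.ndarray, system: ConstraintSystem, tol: float = FEASIBILITY_TOL
) -> ViolationReport:
    """Audit a diet vector against every row and bound of a constraint system.

    The report lists per-row slack (negative = violated), the worst violation,
    and the labels of binding rows (|slack| below ``tol``).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (system.n_foods,):
        raise ValueError(f"solution length {x.shape} does not match system ({system.n_foods})")

    rows: list[RowSlack] = []
    for k, lab in enumerate(system.eq_labels):
        v = float(system.A_eq[k] @ x)
        rows.append(RowSlack(lab, v, float(system.b_eq[k]), float(system.b_eq[k])))
    for k, lab in enumerate(system.in_labels):
        v = float(system.A_in[k] @ x)
        rows.append(RowSlack(lab, v, float(system.lower[k]), float(system.upper[k])))
    for i, fid in enumerate(system.food_ids):
        lo, up = system.x_lower[i], system.x_upper[i]
        if lo > 0 or np.isfinite(up):
            rows.append(RowSlack(f"habit:{fid}", float(x[i]), float(lo), float(up)))

    worst = max((-r.slack for r in rows), default=0.0)
    worst = max(worst, 0.0)
    binding = [r.label for r in rows if abs(r.slack) <= tol]
    return ViolationReport(rows, worst, worst <= tol, binding)


def aggregate_to_main(
    x: np.ndarray, universe: FoodUniverse, categories: Iterable[str] = MAIN_CATEGORIES
) -> pd.DataFrame:
    """Per-main-category totals of quantity (g), cost (EUR), energy (kJ) and
    GHGE (kg CO2e) per capita per day, for a diet vector ``x``.

    The grand totals of the columns equal the ungrouped diet totals exactly
    (same sums in a different order).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (universe.n_foods,):
        raise ValueError("diet vector length does not match the universe")
    df = pd.DataFrame(
        {
            "main_category": universe.main_category,
            "quantity": x,
            "cost": universe.prices * x,
            "energy": universe.energy_density * x,
            "ghge": universe.ghge * x / 1000.0,
        }
    )
    out = df.groupby("main_category", sort=False).sum()
    order = [c for c in categories if c in out.index]
    extra = [c for c in out.index if c not in order]
    return out.loc[order + extra]
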