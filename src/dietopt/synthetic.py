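"""Synthetic food universes and population groups.

The generator emulates the statistical structure the analysis assumes, so
that the whole pipeline is testable without restricted survey inputs:

* 74 food categories mapped to 16 main categories, with animal-source
  categories (Meat, Dairy, Fish, Eggs) carrying elevated prices and GHGE
  intensities and ruminant beef the highest intensity of all;
* 61 bounded nutrients (30 macronutrients including %E-bounded
  protein/fat/carbohydrate/alcohol and a set of indispensable amino acids,
  13 vitamins, 18 minerals including iron), with densities tied to energy
  density plus category affinities, so isocaloric substitutions move
  nutrient intakes smoothly;
* right-skewed (lognormal, zero-inflated for rarely eaten foods)
  person-level consumption yielding P10/P90 food-habit bounds around a
  strictly positive baseline diet;
* a baseline scaled to the target energy level exactly (7311 kJ/d for
  females, 28% higher for males) and consistent with the dairy-beef
  jointness constraint;
* nutrient bounds built around baseline intakes with multiplicative slack,
  guaranteeing that the health-only problem is feasible at the baseline, and
  a stress mode that pushes a few lower bounds above baseline intake to
  force non-trivial optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constraints import DEFAULT_ENERGY_CONVERSION
from .core import (
    DEFAULT_MILK_PER_BEEF,
    FoodCategory,
    FoodUniverse,
    NutrientBounds,
    NutrientDef,
    PopulationGroup,
)

FEMALE_ENERGY_KJ = 7311.0
MALE_ENERGY_RATIO = 1.28

# (main category, n foods, energy kJ/g, price EUR/g, GHGE g/g, baseline g/d
#  per food, %E shares of protein/fat/carbohydrate)
_CATEGORY_PLAN = [
    ("Alcohol", 2, 2.0, 0.0050, 1.2, 70.0, (0.03, 0.00, 0.25)),
    ("Beverages", 3, 0.4, 0.0010, 0.4, 220.0, (0.05, 0.02, 0.80)),
    ("Cereals", 8, 13.0, 0.0020, 0.8, 20.0, (0.14, 0.07, 0.75)),
    ("Diet products", 1, 15.0, 0.0300, 2.0, 2.0, (0.40, 0.20, 0.35)),
    ("Eggs", 1, 6.0, 0.0020, 0.5, 24.0, (0.35, 0.60, 0.02)),
    ("Fats", 7, 32.0, 0.0060, 3.5, 7.0, (0.01, 0.97, 0.01)),
    ("Fish", 2, 6.0, 0.0060, 0.8, 18.0, (0.55, 0.40, 0.01)),
    ("Flavoring", 2, 3.0, 0.0050, 1.0, 5.0, (0.15, 0.15, 0.55)),
    ("Fruits", 7, 2.2, 0.0030, 0.9, 40.0, (0.04, 0.03, 0.88)),
    ("Ingredients", 3, 8.0, 0.0030, 0.8, 4.0, (0.10, 0.10, 0.70)),
    ("Legumes and nuts", 3, 12.0, 0.0080, 1.2, 7.0, (0.28, 0.35, 0.32)),
    ("Meat", 8, 8.0, 0.0045, 2.0, 25.0, (0.45, 0.50, 0.01)),
    ("Dairy", 14, 2.5, 0.0020, 0.5, 40.0, (0.25, 0.45, 0.28)),
    ("Potatoes", 2, 3.5, 0.0015, 0.25, 40.0, (0.08, 0.02, 0.85)),
    ("Sugar", 4, 16.0, 0.0060, 1.5, 8.0, (0.03, 0.15, 0.80)),
    ("Vegetables", 7, 1.2, 0.0040, 1.5, 25.0, (0.15, 0.05, 0.70)),
]

_ANIMAL_CATEGORIES = {"Meat", "Dairy", "Fish", "Eggs"}

# beef-carcass fractions of the named beef-bearing foods
_BEEF_FRACTIONS = {
    "beef": 1.0,
    "offal": 0.88,
    "meat_products": 0.5,
    "sausages": 0.075,
    "sausage_cuts": 0.075,
    "meat_cuts": 0.075,
}
_MEAT_FOOD_NAMES = ["beef", "offal", "meat_products", "sausages", "sausage_cuts",
                    "meat_cuts", "pork", "poultry"]

# raw-milk equivalents (g raw milk per g of product) for dairy foods, cycled
_DAIRY_MILK_EQUIV = [1.0, 1.0, 1.0, 1.1, 2.2, 10.0, 9.0, 1.5, 1.0, 1.2, 6.5, 1.0, 1.0, 2.0]

_AMINO_ACIDS = ["lysine", "threonine", "methionine", "leucine", "isoleucine", "valine"]


@dataclass
class GeneratorConfig:
    """Study conditions emulated by the generator."""

    seed: int = 0
    n_foods: int = 74
    n_main: int = 16
    n_macronutrients: int = 30  # includes the %E macros and the amino acids
    n_vitamins: int = 13
    n_minerals: int = 18
    sex: str = "female"
    group_label: str = "all"
    target_energy_kj: float | None = None  # default: 7311 female, x1.28 male
    animal_price_mult: float = 2.0
    animal_ghge_mult: float = 5.0
    beef_ghge_mult: float = 3.0  # extra ruminant factor on top of the animal one
    beef_price_mult: float = 1.5  # beef is the dearest common protein source
    consumption_sigma: float = 1.0  # lognormal sigma of person-level intake
    n_people: int = 780
    zero_inflation: float = 0.2  # P(zero intake) for rarely eaten foods
    rare_quantile: float = 0.2  # foods below this baseline quantile are "rare"
    slack_lo: float = 0.8
    slack_hi: float = 1.5
    amino_slack_lo: float = 0.55  # pre-safety-margin floor for amino acids
    stress: bool = False
    stress_factor: float = 1.1
    n_stress_nutrients: int = 4
    milk_per_beef: float = DEFAULT_MILK_PER_BEEF

    def __post_init__(self) -> None:
        if self.n_main > self.n_foods:
            raise ValueError("n_main must not exceed n_foods")
        if min(self.animal_price_mult, self.animal_ghge_mult, self.beef_ghge_mult) <= 0:
            raise ValueError("multipliers must be positive")
        if not self.slack_lo < 1.0 < self.slack_hi:
            raise ValueError("slack factors must bracket 1")

    @property
    def energy_target(self) -> float:
        if self.target_energy_kj is not None:
            return self.target_energy_kj
        if self.sex == "male":
            return round(MALE_ENERGY_RATIO * FEMALE_ENERGY_KJ)
        return FEMALE_ENERGY_KJ

    @property
    def n_nutrients(self) -> int:
        return self.n_macronutrients + self.n_vitamins + self.n_minerals


def _food_counts(config: GeneratorConfig) -> list[tuple]:
    """Scale the per-category food counts to n_foods by largest remainder."""
    plan = _CATEGORY_PLAN[: config.n_main]
    base = np.array([row[1] for row in plan], dtype=float)
    exact = base / base.sum() * config.n_foods
    counts = np.maximum(np.floor(exact).astype(int), 1)
    rem = exact - np.floor(exact)
    while counts.sum() < config.n_foods:
        k = int(np.argmax(np.where(counts < 1e9, rem, -1)))
        counts[k] += 1
        rem[k] = -1
    while counts.sum() > config.n_foods:
        k = int(np.argmax(counts))
        counts[k] -= 1
    return [(row, int(c)) for row, c in zip(plan, counts)]


def _nutrient_defs(config: GeneratorConfig) -> list[NutrientDef]:
    defs: list[NutrientDef] = []
    pct_e = [("protein", "Protein"), ("fat", "Fat"),
             ("carbohydrate", "Available carbohydrate"), ("alcohol", "Alcohol")]
    for nid, name in pct_e[: min(4, config.n_macronutrients)]:
        defs.append(NutrientDef(nid, name, "%E", "macronutrient"))
    n_amino = min(len(_AMINO_ACIDS), max(config.n_macronutrients - len(defs), 0))
    for nid in _AMINO_ACIDS[:n_amino]:
        defs.append(NutrientDef(nid, nid.capitalize(), "g/d", "amino_acid"))
    k = 1
    while len(defs) < config.n_macronutrients:
        defs.append(NutrientDef(f"macro_{k:02d}", f"Macronutrient {k}", "g/d", "macronutrient"))
        k += 1
    for k in range(1, config.n_vitamins + 1):
        defs.append(NutrientDef(f"vit_{k:02d}", f"Vitamin {k}", "mg/d", "vitamin"))
    if config.n_minerals >= 1:
        defs.append(NutrientDef("iron", "Iron", "mg/d", "mineral"))
    for k in range(2, config.n_minerals + 1):
        defs.append(NutrientDef(f"min_{k:02d}", f"Mineral {k}", "mg/d", "mineral"))
    return defs


def generate_universe(config: GeneratorConfig) -> FoodUniverse:
    """Generate a reproducible food universe under the configured seed."""
    rng = np.random.default_rng(config.seed)
    nutrient_defs = _nutrient_defs(config)
    conv = DEFAULT_ENERGY_CONVERSION

    foods: list[FoodCategory] = []
    for (row, count) in _food_counts(config):
        cat, _, e_mean, p_mean, g_mean, _, (sp, sf, sc) = row
        slug = cat.lower().replace(" ", "_")
        for k in range(count):
            if cat == "Meat" and k < len(_MEAT_FOOD_NAMES):
                fid = _MEAT_FOOD_NAMES[k]
            else:
                fid = f"{slug}_{k + 1:02d}"
            e = e_mean * rng.lognormal(0.0, 0.25)
            p = p_mean * rng.lognormal(0.0, 0.25)
            g = g_mean * rng.lognormal(0.0, 0.25)
            if cat in _ANIMAL_CATEGORIES:
                p *= config.animal_price_mult
                g *= config.animal_ghge_mult
            beef_fraction = _BEEF_FRACTIONS.get(fid, 0.0)
            if fid == "beef":
                g *= config.beef_ghge_mult
                p *= config.beef_price_mult
            raw_milk = 0.0
            if cat == "Dairy":
                raw_milk = _DAIRY_MILK_EQUIV[k % len(_DAIRY_MILK_EQUIV)] * rng.lognormal(0.0, 0.1)

            # energy-yielding macro densities from per-category %E shares
            defined = {nd.id for nd in nutrient_defs}
            shares = np.clip(np.array([sp, sf, sc]) * rng.lognormal(0.0, 0.15, 3), 0.0, None)
            density: dict[str, float] = {}
            for nid, share, cv in zip(("protein", "fat", "carbohydrate"), shares,
                                      (conv["protein"], conv["fat"], conv["carbohydrate"])):
                density[nid] = share * e / cv
            density["alcohol"] = (0.7 if cat == "Alcohol" else 1e-4) * e / conv["alcohol"]
            for nid in _AMINO_ACIDS:
                density[nid] = density["protein"] * 0.05 * rng.lognormal(0.0, 0.2)
            density = {k: v for k, v in density.items() if k in defined}

            for nd in nutrient_defs:
                if nd.id in density:
                    continue
                boost = 1.0
                if nd.kind == "vitamin" and cat in ("Fruits", "Vegetables"):
                    boost = 3.0
                elif nd.kind == "mineral" and cat in ("Vegetables", "Dairy", "Cereals"):
                    boost = 1.5
                if nd.id == "iron":
                    # haem iron in meat/fish, but cereals and legumes carry
                    # substantial non-haem iron (whole grain, fortification),
                    # which is what makes low-emission iron sourcing possible
                    boost = {"Meat": 3.0, "Fish": 3.0, "Eggs": 2.5,
                             "Legumes and nuts": 2.5, "Cereals": 2.0,
                             "Vegetables": 1.5}.get(cat, 1.0)
                density[nd.id] = 1e-3 * boost * e * rng.lognormal(0.0, 0.4) + 1e-8

            foods.append(
                FoodCategory(
                    id=fid,
                    name=fid.replace("_", " ").capitalize(),
                    main_category=cat,
                    energy_kj_per_g=e,
                    price_eur_per_g=p,
                    ghge_g_per_g=g,
                    nutrient_density=density,
                    beef_fraction=beef_fraction,
                    raw_milk_equiv=raw_milk,
                )
            )

    return FoodUniverse(foods, nutrient_defs, bounds=(), milk_per_beef=config.milk_per_beef)


def generate_group(universe: FoodUniverse, config: GeneratorConfig) -> PopulationGroup:
    """Baseline diet and habit percentiles for one population group.

    The baseline is scaled so total energy hits the target exactly, the
    dairy-beef jointness row is satisfied with margin, and P10 <= x0 <= P90
    holds elementwise (habit bounds are widened to the baseline when the
    sampled percentiles would exclude it).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    scale_of = {row[0]: row[5] for row in _CATEGORY_PLAN}
    x0 = np.array(
        [scale_of[f.main_category] * rng.lognormal(0.0, 0.4) for f in universe.foods]
    )

    # satisfy the dairy-beef jointness row with a 10% margin
    rho = universe.milk_per_beef
    b, r = universe.beef_fraction, universe.raw_milk_equiv
    milk = float(r @ x0)
    beef = float(b @ x0)
    if np.any(r > 0):
        if beef <= 0:
            raise ValueError("universe has dairy but no beef-bearing food")
        need = 1.1 * milk / rho
        if rho * beef < 1.1 * milk:
            x0[b > 0] *= need / beef

    # isocaloric scaling to the target energy level, exactly
    x0 *= config.energy_target / float(universe.energy_density @ x0)

    # person-level lognormal consumption with zero inflation for rare foods
    rare = x0 < np.quantile(x0, config.rare_quantile)
    sigma = config.consumption_sigma
    p10 = np.empty_like(x0)
    p90 = np.empty_like(x0)
    for i, xi in enumerate(x0):
        draws = rng.lognormal(np.log(xi) - sigma**2 / 2.0, sigma, config.n_people)
        if rare[i] and config.zero_inflation > 0:
            draws[rng.random(config.n_people) < config.zero_inflation] = 0.0
        p10[i], p90[i] = np.percentile(draws, [10, 90])
    p10 = np.minimum(p10, x0)
    p90 = np.maximum(p90, x0)

    return PopulationGroup(sex=config.sex, label=config.group_label, x0=x0, p10=p10, p90=p90)


def generate_feasible_bounds(
    universe: FoodUniverse, group: PopulationGroup, config: GeneratorConfig
) -> list[NutrientBounds]:
    """Nutrient bounds bracketing the baseline-implied intakes.

    With default slack the baseline diet is feasible for the health-only
    problem by construction.  In stress mode the lower bounds of a few
    vitamins/minerals are raised above baseline intake, so the baseline is
    deliberately infeasible and the optimizer must reshape the diet.
    ``%E`` bounds are stated in percent of energy; amino-acid floors use a
    wider pre-safety-margin slack so that the builder's safety multiplier
    still leaves the baseline feasible.

    Stress floors are chosen constructively: the tightest scenario (GHGE cap
    at half of baseline, with the food-habit box) is checked for a feasible
    point, and any stressed floor that would make it empty is pulled back
    toward the baseline intake.  The generator thereby honours its
    feasibility contract on every seed while still forcing non-trivial
    optimization wherever the instance allows it.
    """
    conv = DEFAULT_ENERGY_CONVERSION
    a = universe.nutrient_matrix()
    e0 = group.baseline_energy(universe)
    intakes = a @ group.x0

    stress_ids: set[str] = set()
    if config.stress:
        eligible = [n.id for n in universe.nutrients if n.kind in ("vitamin", "mineral")]
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        k = min(config.n_stress_nutrients, len(eligible))
        stress_ids = set(rng.choice(eligible, size=k, replace=False))

    bounds: list[NutrientBounds] = []
    for j, nut in enumerate(universe.nutrients):
        t = float(intakes[j])
        if t <= 0:
            continue
        if nut.unit == "%E":
            pct = 100.0 * conv[nut.id] * t / e0
            lo, hi = config.slack_lo * pct, min(config.slack_hi * pct, 100.0)
            if nut.id == "alcohol":
                lo = None  # recommendations cap alcohol; they never require it
        elif nut.kind == "amino_acid":
            lo, hi = config.amino_slack_lo * t, config.slack_hi * t
        else:
            lo, hi = config.slack_lo * t, config.slack_hi * t
        if nut.id in stress_ids:
            lo = config.stress_factor * (pct if nut.unit == "%E" else t)
        bounds.append(NutrientBounds(nut.id, group.sex, lo, hi, source="recommended"))

    if stress_ids:
        bounds = _repair_stress_floors(universe, group, bounds, stress_ids, intakes)
    return bounds


def _repair_stress_floors(universe, group, bounds, stress_ids, intakes):
    """Pull stressed floors back toward baseline until the tightest scenario
    (GHGE -50%, habit box) admits a feasible point."""
    from .constraints import build
    from .core import HEALTH_GHGE_MINUS50
    from .optimize import _feasible_point

    idx = {n.id: j for j, n in enumerate(universe.nutrients)}
    for _ in range(8):
        universe.bounds = bounds
        system = build(universe, group, HEALTH_GHGE_MINUS50, "min_deviation")
        if _feasible_point(system):
            return bounds
        new = []
        for b in bounds:
            if b.nutrient_id in stress_ids and b.lower is not None:
                # halve the excess of the floor over the baseline intake;
                # once negligible, stop stressing this nutrient altogether
                t = float(intakes[idx[b.nutrient_id]])
                pulled = t + 0.5 * (b.lower - t)
                if pulled <= t * 1.001:
                    pulled = 0.999 * t
                new.append(NutrientBounds(b.nutrient_id, b.sex, pulled, b.upper, b.source))
            else:
                new.append(b)
        bounds = new
    universe.bounds = bounds
    return bounds


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[FoodUniverse, PopulationGroup]:
    """Universe (with bounds attached) and group for one configuration."""
    universe = generate_universe(config)
    group = generate_group(universe, config)
    universe.bounds = generate_feasible_bounds(universe, group, config)
    return universe, group
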