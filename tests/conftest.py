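import numpy as np
import pytest

from dietopt import FoodCategory, FoodUniverse, GeneratorConfig, NutrientBounds, NutrientDef
from dietopt import PopulationGroup, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Feasibility-by-construction universe + group (female defaults)."""
    return generate_dataset(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def stress_dataset():
    """Stress-mode instance where the baseline is deliberately infeasible."""
    return generate_dataset(GeneratorConfig(seed=7, stress=True))


@pytest.fixture()
def tiny_universe():
    """Hand-built 4-food universe with one nutrient of each special kind."""
    nutrients = [
        NutrientDef("fat", "Fat", "%E", "macronutrient"),
        NutrientDef("lysine", "Lysine", "g/d", "amino_acid"),
        NutrientDef("iron", "Iron", "mg/d", "mineral"),
        NutrientDef("fiber", "Fiber", "g/d", "macronutrient"),
    ]
    foods = [
        FoodCategory("bread", "Bread", "Cereals", 10.0, 0.002, 0.8,
                     {"fat": 0.02, "lysine": 0.003, "iron": 0.02, "fiber": 0.08}),
        FoodCategory("beef", "Beef", "Meat", 8.0, 0.01, 30.0,
                     {"fat": 0.15, "lysine": 0.02, "iron": 0.03, "fiber": 0.0},
                     beef_fraction=1.0),
        FoodCategory("milk", "Milk", "Dairy", 2.5, 0.001, 1.2,
                     {"fat": 0.035, "lysine": 0.003, "iron": 0.001, "fiber": 0.0},
                     raw_milk_equiv=1.0),
        FoodCategory("carrot", "Carrot", "Vegetables", 1.5, 0.003, 0.4,
                     {"fat": 0.002, "lysine": 0.0005, "iron": 0.004, "fiber": 0.03}),
    ]
    bounds = [
        NutrientBounds("fat", "female", 20.0, 40.0),
        NutrientBounds("lysine", "female", 1.0, None),
        NutrientBounds("iron", "female", 5.0, 30.0),
        NutrientBounds("fiber", "female", None, 50.0),
    ]
    return FoodUniverse(foods, nutrients, bounds)


@pytest.fixture()
def tiny_group(tiny_universe):
    x0 = np.array([150.0, 80.0, 400.0, 120.0])
    return PopulationGroup(
        sex="female", label="all", x0=x0, p10=0.5 * x0, p90=2.0 * x0
    )
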