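"""Delimited-text input/output for the model's data objects.

Schemas:

* ``foods.csv``: id, name, main_category, energy_kj_per_g, price_eur_per_g,
  ghge_g_per_g, beef_fraction, raw_milk_equiv
* ``densities.csv``: food_id plus one column per nutrient id (amount per g)
* ``nutrients.csv``: id, name, unit, kind
* ``bounds.csv``: nutrient_id, sex, lower, upper, source (blank = absent)
* ``group.csv``: food_id, x0, p10, p90 (plus sex/label columns on every row)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DietSolution,
    FoodCategory,
    FoodUniverse,
    NutrientBounds,
    NutrientDef,
    PopulationGroup,
)


def write_universe(universe: FoodUniverse, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "id": f.id,
                "name": f.name,
                "main_category": f.main_category,
                "energy_kj_per_g": f.energy_kj_per_g,
                "price_eur_per_g": f.price_eur_per_g,
                "ghge_g_per_g": f.ghge_g_per_g,
                "beef_fraction": f.beef_fraction,
                "raw_milk_equiv": f.raw_milk_equiv,
            }
            for f in universe.foods
        ]
    ).to_csv(outdir / "foods.csv", index=False)
    dens = pd.DataFrame(
        universe.nutrient_matrix().T, columns=universe.nutrient_ids
    )
    dens.insert(0, "food_id", universe.food_ids)
    dens.to_csv(outdir / "densities.csv", index=False)
    pd.DataFrame(
        [{"id": n.id, "name": n.name, "unit": n.unit, "kind": n.kind} for n in universe.nutrients]
    ).to_csv(outdir / "nutrients.csv", index=False)
    pd.DataFrame(
        [
            {
                "nutrient_id": b.nutrient_id,
                "sex": b.sex,
                "lower": b.lower,
                "upper": b.upper,
                "source": b.source,
            }
            for b in universe.bounds
        ]
    ).to_csv(outdir / "bounds.csv", index=False)
    with open(outdir / "universe.json", "w") as fh:
        json.dump({"milk_per_beef": universe.milk_per_beef}, fh)


def read_universe(indir: str | Path) -> FoodUniverse:
    indir = Path(indir)
    foods_df = pd.read_csv(indir / "foods.csv")
    dens_df = pd.read_csv(indir / "densities.csv").set_index("food_id")
    nut_df = pd.read_csv(indir / "nutrients.csv")
    bounds_path = indir / "bounds.csv"
    meta = {}
    if (indir / "universe.json").exists():
        meta = json.loads((indir / "universe.json").read_text())

    nutrients = [NutrientDef(r.id, r.name, r.unit, r.kind) for r in nut_df.itertuples()]
    foods = []
    for r in foods_df.itertuples():
        density = dens_df.loc[r.id].to_dict() if r.id in dens_df.index else {}
        foods.append(
            FoodCategory(
                id=r.id,
                name=r.name,
                main_category=r.main_category,
                energy_kj_per_g=r.energy_kj_per_g,
                price_eur_per_g=r.price_eur_per_g,
                ghge_g_per_g=r.ghge_g_per_g,
                nutrient_density=density,
                beef_fraction=r.beef_fraction,
                raw_milk_equiv=r.raw_milk_equiv,
            )
        )
    bounds = []
    if bounds_path.exists():
        for r in pd.read_csv(bounds_path).itertuples():
            bounds.append(
                NutrientBounds(
                    r.nutrient_id,
                    r.sex,
                    None if pd.isna(r.lower) else float(r.lower),
                    None if pd.isna(r.upper) else float(r.upper),
                    r.source,
                )
            )
    return FoodUniverse(foods, nutrients, bounds, meta.get("milk_per_beef", 33.9))


def write_group(group: PopulationGroup, universe: FoodUniverse, path: str | Path) -> None:
    pd.DataFrame(
        {
            "food_id": universe.food_ids,
            "x0": group.x0,
            "p10": group.p10,
            "p90": group.p90,
            "sex": group.sex,
            "label": group.label,
        }
    ).to_csv(path, index=False)


def read_group(path: str | Path, universe: FoodUniverse) -> PopulationGroup:
    df = pd.read_csv(path).set_index("food_id").loc[universe.food_ids]
    return PopulationGroup(
        sex=str(df["sex"].iloc[0]),
        label=str(df["label"].iloc[0]),
        x0=df["x0"].to_numpy(),
        p10=df["p10"].to_numpy(),
        p90=df["p90"].to_numpy(),
    )


def write_solution(solution: DietSolution, path: str | Path) -> None:
    payload = solution.to_dict()
    if solution.report is not None:
        payload["verification"] = solution.report.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
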