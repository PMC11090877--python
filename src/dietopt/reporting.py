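"""Result surfaces: per-main-category tables with shares, summary ratios,
and diet-diversity counts."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import DietSolution, FoodUniverse, PopulationGroup, aggregate_to_main


@dataclass
class ScenarioReport:
    """Per-main-category cost/energy/GHGE with shares for one scenario cell."""

    group_label: str
    sex: str
    scenario: str
    table: pd.DataFrame  # index main_category; value + share columns per metric

    def totals(self) -> dict[str, float]:
        return {m: float(self.table[m].sum()) for m in ("cost", "energy", "ghge")}


def shares(values: pd.Series | np.ndarray) -> np.ndarray:
    """Per-category fractions of the total. The total must be positive."""
    v = np.asarray(values, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("cannot form shares of a nonpositive total")
    return v / total


def scenario_report(
    x: np.ndarray,
    universe: FoodUniverse,
    group: PopulationGroup,
    scenario: str,
) -> ScenarioReport:
    agg = aggregate_to_main(x, universe)
    table = agg[["cost", "energy", "ghge"]].copy()
    for m in ("cost", "energy", "ghge"):
        table[f"{m}_share"] = shares(table[m])
    return ScenarioReport(group.label, group.sex, scenario, table)


def summary_ratios(
    baseline_totals: Mapping[str, float], solution_totals: Mapping[str, float]
) -> dict[str, dict[str, float]]:
    """Percent-of-baseline and percent-change for each shared metric.

    Values are kept at full precision; rounding to integer percent is a
    presentation step left to the caller.
    """
    out: dict[str, dict[str, float]] = {}
    for metric, base in baseline_totals.items():
        if metric not in solution_totals:
            continue
        if base <= 0:
            raise ValueError(f"baseline total for {metric!r} must be positive")
        pct = 100.0 * solution_totals[metric] / base
        out[metric] = {"percent_of_baseline": pct, "percent_change": pct - 100.0}
    return out


def nonzero_food_count(x: np.ndarray | DietSolution, threshold: float = 0.0) -> int:
    """Number of foods consumed above a threshold (diet-diversity count)."""
    if isinstance(x, DietSolution):
        x = x.x
    return int(np.sum(np.asarray(x, dtype=float) > threshold))


def solution_frame(
    baseline: np.ndarray, solution: np.ndarray, universe: FoodUniverse
) -> pd.DataFrame:
    """Per-food table mirroring the solution-vs-baseline result layout:
    quantity, GHGE and cost columns for both diets."""
    baseline = np.asarray(baseline, dtype=float)
    solution = np.asarray(solution, dtype=float)
    return pd.DataFrame(
        {
            "food_id": universe.food_ids,
            "main_category": universe.main_category,
            "qty_base_g": baseline,
            "qty_solution_g": solution,
            "ghge_base_g": universe.ghge * baseline,
            "ghge_solution_g": universe.ghge * solution,
            "cost_base_eur": universe.prices * baseline,
            "cost_solution_eur": universe.prices * solution,
        }
    )
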