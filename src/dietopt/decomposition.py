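"""Additive intra-/inter-category decomposition of diet-change effects.

For a metric with per-food unit values ``v_i`` (price in EUR/g or GHGE
intensity in g CO2e/g) and a main category C, write ``Q_C = sum_{i in C} x_i``
and ``V_C = sum_{i in C} v_i x_i``, and let ``vbar_C0 = V_C0 / Q_C0`` be the
baseline mean unit value of the category.  The change in the category's
contribution between a baseline diet x0 and a solution diet x1 splits
exactly into

    inter_C = vbar_C0 * (Q_C1 - Q_C0)        (quantity shifted across
                                              categories, valued at the
                                              baseline category mix)
    intra_C = V_C1 - vbar_C0 * Q_C1          (re-composition within the
                                              category at final quantity)

with ``intra_C + inter_C = V_C1 - V_C0`` holding identically.  This is the
Laspeyres-type two-term additive scheme; a category consumed not at all at
baseline has no mean unit value, so its whole change is booked as inter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import FoodUniverse, MAIN_CATEGORIES


@dataclass(frozen=True)
class DecompositionRow:
    main_category: str
    metric: str  # cost | ghge
    delta_total: float
    intra: float
    inter: float


def decompose(
    x0: np.ndarray,
    x1: np.ndarray,
    unit_values: np.ndarray,
    main_of: Sequence[str],
    metric: str = "cost",
) -> list[DecompositionRow]:
    """Per-main-category intra/inter split of the change in sum_i v_i x_i."""
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    v = np.asarray(unit_values, dtype=float)
    if not (x0.shape == x1.shape == v.shape):
        raise ValueError("x0, x1 and unit values must have equal length")
    if len(main_of) != x0.size:
        raise ValueError("main-category mapping does not cover every food")
    if np.any(x0 < -1e-9) or np.any(x1 < -1e-9):
        raise ValueError("diet vectors must be nonnegative")
    x0, x1 = np.clip(x0, 0.0, None), np.clip(x1, 0.0, None)

    cats = list(dict.fromkeys(main_of))
    rows = []
    main_arr = np.asarray(main_of)
    for c in cats:
        m = main_arr == c
        q0, q1 = x0[m].sum(), x1[m].sum()
        v0, v1 = float(v[m] @ x0[m]), float(v[m] @ x1[m])
        if q0 > 0:
            vbar0 = v0 / q0
            inter = vbar0 * (q1 - q0)
            intra = v1 - vbar0 * q1
        else:
            inter = v1 - v0
            intra = 0.0
        rows.append(DecompositionRow(c, metric, v1 - v0, intra, inter))
    return rows


def decomposition_table(
    x0: np.ndarray,
    solutions: Mapping[str, np.ndarray],
    universe: FoodUniverse,
) -> pd.DataFrame:
    """Long table of intra/inter contributions per main category, metric and
    scenario, with a TOTAL row per (metric, scenario) block.

    Cost is reported in EUR/cap/d and GHGE in kg CO2e/cap/d.
    """
    metrics = {"cost": universe.prices, "ghge": universe.ghge / 1000.0}
    main_of = universe.main_category
    order = [c for c in MAIN_CATEGORIES if c in main_of]
    records = []
    for metric, v in metrics.items():
        for scenario, x1 in solutions.items():
            rows = decompose(x0, x1, v, main_of, metric)
            rows.sort(key=lambda r: order.index(r.main_category) if r.main_category in order else 99)
            for r in rows:
                records.append(
                    {
                        "main_category": r.main_category,
                        "metric": metric,
                        "scenario": scenario,
                        "delta_total": r.delta_total,
                        "intra": r.intra,
                        "inter": r.inter,
                    }
                )
            records.append(
                {
                    "main_category": "TOTAL",
                    "metric": metric,
                    "scenario": scenario,
                    "delta_total": sum(r.delta_total for r in rows),
                    "intra": sum(r.intra for r in rows),
                    "inter": sum(r.inter for r in rows),
                }
            )
    return pd.DataFrame.from_records(records)


def intra_share(intra_total: float, inter_total: float) -> float:
    """Share (in %) of a total change attributable to within-category
    substitution, computed on magnitudes: 100*|intra| / (|intra| + |inter|)."""
    denom = abs(intra_total) + abs(inter_total)
    if denom == 0:
        raise ValueError("no change to attribute")
    return 100.0 * abs(intra_total) / denom
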