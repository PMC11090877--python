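"""Data-construction arithmetic for the diet models.

Covers the steps that turn survey-style raw records into model inputs:
unit-value prices from expenditure diaries, consumption-share nutrient
aggregation, OECD-equivalized income for quantile strata, and empirical
habit percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

# OECD equivalence scale weights
_FIRST_ADULT_W = 1.0
_EXTRA_ADULT_W = 0.7
_MINOR_W = 0.5


@dataclass(frozen=True)
class ExpenditureRecord:
    """One expenditure observation for a COICOP-like source category."""

    source_category: str
    expenditure: float  # EUR
    quantity: float  # g
    target_food_id: str | None = None

    def __post_init__(self) -> None:
        if self.expenditure < 0:
            raise ValueError("expenditure must be nonnegative")


@dataclass(frozen=True)
class HouseholdRecord:
    """Household income and composition for equivalized-income strata."""

    total_income: float  # EUR per year
    n_adults: int
    n_minors: int = 0

    def __post_init__(self) -> None:
        if self.n_adults < 0 or self.n_minors < 0:
            raise ValueError("household member counts must be nonnegative")


def unit_value_price(records: Sequence[ExpenditureRecord]) -> float:
    """Unit-value price (EUR/g) of one source category.

    Pooled ratio of total expenditure to total physical quantity over the
    sample — not the mean of per-record ratios.
    """
    if not records:
        raise ValueError("no expenditure records")
    total_q = sum(r.quantity for r in records)
    if total_q <= 0:
        raise ValueError("total quantity must be positive to form a unit value")
    return sum(r.expenditure for r in records) / total_q


def category_price(prices: Sequence[float], weights: Sequence[float]) -> float:
    """Price of a food category as the weighted mean of matched source prices.

    Weights are typically the purchased quantities of the matched source
    categories.  Raises if there is no matched source with positive weight
    (the food is then unpriced and needs a fallback price).
    """
    prices = np.asarray(prices, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if prices.shape != weights.shape:
        raise ValueError("prices and weights must have the same length")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if prices.size == 0 or weights.sum() <= 0:
        raise ValueError("food has no priced source category (unpriced)")
    return float(weights @ prices / weights.sum())


def aggregate_nutrients(intakes: Sequence[float], densities: np.ndarray) -> np.ndarray:
    """Category nutrient-density vector from item intakes and item densities.

    ``densities`` is (n_items, n_nutrients); each item is weighted by its
    share of the category's total consumption, so the result lies in the
    convex hull of the item density vectors.
    """
    q = np.asarray(intakes, dtype=float)
    d = np.atleast_2d(np.asarray(densities, dtype=float))
    if q.ndim != 1 or d.shape[0] != q.size:
        raise ValueError("intakes and densities are inconsistent")
    total = q.sum()
    if total <= 0:
        raise ValueError("zero category consumption")
    return (q / total) @ d


def equivalized_income(h: HouseholdRecord) -> float:
    """Household income per OECD consumption unit (1.0 / 0.7 / 0.5 weights)."""
    if h.n_adults < 1:
        raise ValueError("household must contain at least one adult")
    units = _FIRST_ADULT_W + _EXTRA_ADULT_W * (h.n_adults - 1) + _MINOR_W * h.n_minors
    return h.total_income / units


def assign_strata(values: Sequence[float], n_strata: int) -> np.ndarray:
    """Assign each value to one of ``n_strata`` quantile strata (0-based).

    Cut points are the empirical quantiles at k/n_strata; values equal to a
    cut point fall in the lower stratum, which makes the assignment
    deterministic and invariant to monotone rescaling.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to stratify")
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    cuts = np.quantile(v, np.arange(1, n_strata) / n_strata)
    return np.searchsorted(cuts, v, side="left")


def habit_percentiles(
    sample: Sequence[float], probs: tuple[float, float] = (0.10, 0.90)
) -> tuple[float, float]:
    """Empirical (P10, P90) habit bounds from a per-person consumption sample.

    Linear interpolation between order statistics (inclusive, type-7).
    """
    s = np.asarray(sample, dtype=float)
    if s.size == 0:
        raise ValueError("empty consumption sample")
    if np.any(s < 0):
        raise ValueError("consumption values must be nonnegative")
    lo, hi = np.quantile(s, probs)
    return float(lo), float(hi)
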