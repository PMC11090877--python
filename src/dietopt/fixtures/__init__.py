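"""Packaged worked-example tables (CSV transcriptions of published results).

Loaders return pandas DataFrames.  The per-food minimum-cost table stores
GHGE in g CO2e/cap/d (its per-food cells were originally printed in kg and
are converted on transcription; the totals row was printed in g).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_PKG = "dietopt.fixtures"


def _read(name: str) -> pd.DataFrame:
    with resources.files(_PKG).joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_min_cost_male() -> tuple[pd.DataFrame, pd.Series]:
    """(per-food rows, totals row) of the minimum-cost diet table, adult male."""
    df = _read("min_cost_male.csv")
    totals = df[df.food_id == "TOTAL"].iloc[0]
    return df[df.food_id != "TOTAL"].reset_index(drop=True), totals


def load_min_deviation_female(metric: str) -> tuple[pd.DataFrame, pd.Series]:
    """(per-category rows, totals row) for metric in {cost, energy, ghge},
    minimum-deviation scenarios for an adult female."""
    if metric not in ("cost", "energy", "ghge"):
        raise ValueError(f"unknown metric {metric!r}")
    df = _read(f"min_deviation_{metric}_female.csv")
    totals = df[df.main_category == "TOTAL"].iloc[0]
    return df[df.main_category != "TOTAL"].reset_index(drop=True), totals


def load_decomposition_male() -> pd.DataFrame:
    """Long-format intra/inter decomposition of cost and GHGE changes, male."""
    return _read("decomposition_male.csv")
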