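"""Headline figures recomputed from the packaged worked-example tables.

Every quantity here is computed at call time by running the package's
reporting/decomposition machinery on the fixture tables; nothing is merely
transcribed.  Percentages are rounded to integers at the end, matching the
presentation convention of the source tables.
"""

from __future__ import annotations

from . import fixtures
from .decomposition import intra_share
from .reporting import nonzero_food_count, shares, summary_ratios


def compute_headline_figures() -> dict[str, float]:
    out: dict[str, float] = {}

    # --- minimum-cost model, average adult male ---------------------------
    foods, totals = fixtures.load_min_cost_male()
    ratios = summary_ratios(
        {"cost": totals.cost_base_eur, "ghge": totals.ghge_base_g},
        {"cost": totals.cost_mincost_eur, "ghge": totals.ghge_mincost_g},
    )
    out["min_cost_cost_pct_of_baseline_male"] = round(ratios["cost"]["percent_of_baseline"])
    out["min_cost_ghge_pct_of_baseline_male"] = round(ratios["ghge"]["percent_of_baseline"])
    out["min_cost_n_foods_male"] = nonzero_food_count(foods["qty_mincost_g"].to_numpy())

    # --- minimum-deviation model, average adult female --------------------
    cost_rows, cost_totals = fixtures.load_min_deviation_female("cost")
    ghge_rows, ghge_totals = fixtures.load_min_deviation_female("ghge")
    energy_rows, energy_totals = fixtures.load_min_deviation_female("energy")

    cost_r = summary_ratios(
        {"health_only": cost_totals.baseline, "ghge50": cost_totals.baseline},
        {"health_only": cost_totals.health_only, "ghge50": cost_totals.ghge50},
    )
    out["min_dev_cost_change_pct_health_only_female"] = round(
        cost_r["health_only"]["percent_change"]
    )
    out["min_dev_cost_change_pct_ghge50_female"] = round(cost_r["ghge50"]["percent_change"])
    ghge_r = summary_ratios(
        {"health_only": ghge_totals.baseline}, {"health_only": ghge_totals.health_only}
    )
    out["min_dev_ghge_change_pct_health_only_female"] = round(
        ghge_r["health_only"]["percent_change"]
    )

    out["min_dev_energy_total_kj_female"] = float(energy_totals.ghge50)
    out["ghge50_cap_kg_female"] = 0.5 * float(ghge_totals.baseline)
    out["ghge50_total_kg_female"] = float(ghge_totals.ghge50)

    energy_shares = shares(energy_rows["ghge50"].to_numpy())
    idx = {c: k for k, c in enumerate(energy_rows["main_category"])}
    out["cereals_energy_share_pct_ghge50_female"] = round(100.0 * energy_shares[idx["Cereals"]])
    out["meat_energy_share_pct_ghge50_female"] = round(100.0 * energy_shares[idx["Meat"]])

    # --- decomposition, average adult male --------------------------------
    dec = fixtures.load_decomposition_male()
    tot = dec[(dec.main_category == "TOTAL") & (dec.metric == "ghge") & (dec.scenario == "ghge33")]
    out["intra_share_ghge_reduction_pct_ghge33_male"] = round(
        intra_share(float(tot.intra.iloc[0]), float(tot.inter.iloc[0]))
    )
    return out


#: published values the worked example should land on (used by the
#: ``fixtures-check`` CLI verb and the regression test)
EXPECTED_HEADLINE_FIGURES = {
    "min_cost_cost_pct_of_baseline_male": 27,
    "min_cost_ghge_pct_of_baseline_male": 27,
    "min_cost_n_foods_male": 12,
    "min_dev_cost_change_pct_health_only_female": -2,
    "min_dev_cost_change_pct_ghge50_female": -27,
    "min_dev_ghge_change_pct_health_only_female": -15,
    "min_dev_energy_total_kj_female": 7311.0,
    "ghge50_cap_kg_female": 1.89,
    "ghge50_total_kg_female": 1.89,
    "cereals_energy_share_pct_ghge50_female": 36,
    "meat_energy_share_pct_ghge50_female": 1,
    "intra_share_ghge_reduction_pct_ghge33_male": 46,
}
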