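# dietopt

Optimization models for nutritionally adequate, affordable, low-emission
diets, built the way they are used in quantitative nutrition and
sustainable-diet research: a food universe of 74 ingredient-level categories
(reported through 16 main categories) is searched for diets that satisfy
~61 nutrient bounds, stay isocaloric, respect a greenhouse-gas cap and the
dairy–beef jointness of the food system, and — in the culturally
constrained variant — stay within observed food habits.

## The two models

Let `x` be the diet vector (g/capita/day over the food categories), `e_i`
the energy density (kJ/g), `p_i` the price (EUR/g), `g_i` the GHGE
intensity (g CO2e/g) and `a_ji` the density of nutrient `j` in food `i`.

**Minimum-cost model (LP)**

```
min_x  Σ_i p_i x_i
s.t.   Σ_i e_i x_i = E0                   (isocaloric at the baseline level)
       L_j ≤ Σ_i a_ji x_i ≤ U_j          (nutrient adequacy and safety)
       Σ_i g_i x_i ≤ θ·G0                (GHGE cap, θ ∈ {2/3, 1/2}, optional)
       ρ Σ_i b_i x_i − Σ_i r_i x_i ≥ 0   (dairy–beef jointness, ρ = 33.9)
       x ≥ 0
```

**Minimum-deviation model (QP)** replaces the objective with the sum of
squared relative deviations from the observed baseline diet `x⁰`,

```
min_x  Σ_i ((x_i − x_i⁰) / x_i⁰)²
```

subject to the same constraints plus food-habit box bounds
`P10_i ≤ x_i ≤ P90_i` (the 10th/90th centiles of the observed consumption
distribution). The Hessian `diag(2/x_i⁰²)` is positive definite, so the QP
is strictly convex and has a unique global solution.

Nutrients bounded in percent of energy (%E) are linearized against the
fixed energy level; amino-acid floors carry a 24 % safety margin; the
female iron floor is pinned to the baseline iron intake. Scenarios:
`health_only` (no cap), `health_ghge_minus33` (θ = 2/3),
`health_ghge_minus50` (θ = 1/2).

The package also implements the survey-side arithmetic (unit-value prices
from expenditure diaries, consumption-share nutrient aggregation,
OECD-equivalized income strata, empirical habit percentiles), an exact
Laspeyres-type additive decomposition of cost/GHGE changes into intra- and
inter-category substitution effects, reporting tables with shares, a
synthetic-data generator that emulates the survey inputs with guaranteed
feasibility, and a CLI.

## Worked example

```
$ dietopt generate --seed 1 --stress --outdir scratch/demo
wrote dataset (74 foods, 61 nutrients) to scratch/demo
$ dietopt solve --data scratch/demo --scenario health_ghge_minus50 --model min_deviation
min_deviation health_ghge_minus50: status=optimal objective=19.3977 cost=4.83 EUR/d energy=7311 kJ/d ghge=2.02 kg/d
$ dietopt solve --data scratch/demo --scenario health_only --model min_cost
min_cost health_only: status=optimal objective=1.63086 cost=1.63 EUR/d energy=7311 kJ/d ghge=0.78 kg/d
```

The first solve finds the culturally constrained diet closest to the
baseline that halves emissions: it stays isocaloric (7311 kJ/d, the female
baseline energy), attains the cap exactly (2.02 = 0.5 × 4.03 kg CO2e/d) and
costs 4.83 EUR/d against a baseline of 7.65 EUR/d — tightening the
emission cap makes the adequate diet *cheaper*, because the displaced
animal-source foods are the expensive ones. The second solve shows the
unconstrained cost floor: a nutritionally adequate diet at 21 % of the
baseline cost and 19 % of its emissions, but concentrated on a handful of
cheap staples.

The same mechanics run on the packaged worked-example tables
(transcriptions of published baseline/solution tables for an average adult
male and female):

```
$ dietopt fixtures-check
ok   min_cost_cost_pct_of_baseline_male: computed=27 expected=27
ok   min_cost_n_foods_male: computed=12 expected=12
ok   min_dev_ghge_change_pct_health_only_female: computed=-15 expected=-15
...
```

`dietopt run-all --seed 0 --outdir out/` solves the full
design (2 sexes × 7 population groups × 3 scenarios × 2 models = 84 cells)
and writes per-cell reports, decomposition tables and a manifest.

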