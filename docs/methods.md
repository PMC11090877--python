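# Methods

## Models

Two diet-optimization problems share one linear constraint system and
differ only in their objective.

The **minimum-cost model** minimizes `Σ p_i x_i` over diets
`x ∈ R^n_{≥0}` (g/capita/day, n = 74 food categories by default). With the
isocaloric equality and nonnegative prices the feasible set is compact, so
the LP always attains its optimum; the solution diet may be non-unique
(degenerate optima), so only the objective value is treated as contractual
and reported food lists are "a" minimum-cost diet.

The **minimum-deviation model** minimizes `Σ ((x_i − x_i⁰)/x_i⁰)²`, the sum
of squared relative deviations from the observed baseline `x⁰`. The
curvature matrix `diag(2/x_i⁰²)` is positive definite whenever `x⁰ > 0`
elementwise, making the program strictly convex with a unique global
minimum. Foods with zero baseline intake are rejected with an error naming
the food, because a relative deviation from zero is undefined; the
synthetic generator guarantees strictly positive baselines.

## Constraint system

* **Isocaloric equality** `Σ e_i x_i = E0` with `E0 = Σ e_i x_i⁰`. All
  simulations hold energy at its observed level; the models study diet
  *composition*, not energy intake.
* **Nutrient rows**, one two-sided row per bounded nutrient and sex.
  Bounds stated in percent of energy are linearized under the isocaloric
  equality: a floor of `L` %E becomes `Σ (c_j a_ji) x_i ≥ L/100 · E0`,
  with fixed energy-conversion factors `c_j` (kJ per g: fat 37, protein 17,
  available carbohydrate 17, alcohol 29; overridable in `BuilderConfig`).
  Amino-acid floors are multiplied by a 1.24 safety margin, the
  conservative choice appropriate when constraining group-mean intakes
  rather than usual individual intakes. For females the iron floor is
  replaced by the baseline iron intake `Σ a_iron,i x_i⁰`: under the
  isocaloric equality this is equivalent to requiring the iron
  *concentration* of the current diet, and it can never make the baseline
  infeasible.
* **GHGE cap** `Σ g_i x_i ≤ θ·G0`, present only when the scenario sets
  θ (2/3 for the −33 % scenario, 1/2 for −50 %). Tightening θ nests the
  feasible sets, which is what makes the optimal deviation monotone in θ.
* **Dairy–beef jointness** `ρ Σ b_i x_i − Σ r_i x_i ≥ 0`, where `b_i` is
  the beef-carcass fraction of food i (beef 1.0, offal 0.88, meat products
  0.5, sausages/sausage cuts/meat cuts 0.075, otherwise 0), `r_i` the raw-
  milk equivalent of dairy foods (g raw milk per g of product) and
  ρ = 33.9 g raw milk co-produced per g of beef carcass in a
  dairy-dominated chain. A dairy-consuming diet therefore implies a
  minimum beef-carcass off-take. The row is included in both models, since
  it describes the food system rather than a cultural preference. A
  universe containing dairy but no beef-bearing food is rejected as
  structurally infeasible for dairy-containing diets.
* **Food-habit box** `P10 ≤ x ≤ P90` (empirical 10th/90th consumption
  centiles), applied to the minimum-deviation model only; the minimum-cost
  model gets plain nonnegativity.

## Solvers and numerical choices

The LP is solved with HiGHS via `scipy.optimize.linprog`; two-sided rows
are split into upper-bound pairs. The QP is solved in the original
variables (no `z = x/x⁰` substitution) with analytic gradient and Hessian:
`trust-constr` by default, SLSQP as an alternative back-end retained as a
uniqueness cross-check. Because interior-style iterations stop within
~1e-5 of the constrained optimum, every QP solve is finished by an
**active-set polish**: the constraints the iterate sits on seed a working
set, the KKT equality system of that set is solved exactly (one linear
solve, the Hessian being diagonal), violated constraints are added and
wrong-signed multipliers dropped until the KKT conditions hold. The
polished point is accepted only if it is feasible and no worse. If the
baseline `x⁰` itself is feasible it is returned directly — it is the exact
unconstrained minimizer of a strictly convex objective.

Feasibility and binding tolerances are 1e-6 on constraint rows
(conventional for double-precision LP/QP); solver optimality tolerance
1e-9. Totals (cost, energy, GHGE) are always recomputed from the solution
vector, never copied from solver internals, and every returned solution
carries a full per-row slack audit. Components of the solution within the
feasibility tolerance below zero are snapped to zero. On infeasibility the
constraint family (energy / nutrient / ghge / dairy_beef / habit) whose
isolated removal restores feasibility is reported — a one-at-a-time
relaxation, deliberately cheaper than a full irreducible infeasible
subsystem.

Units: quantities g/cap/d; prices stored EUR/g and reported EUR/cap/d;
GHGE intensities stored g CO2e per g and diet totals reported kg CO2e/cap/d;
energy kJ. The packaged per-food minimum-cost table stores GHGE cells in
grams (the printed per-food cells were in kg despite the table's g header;
the printed totals row, in grams, is kept verbatim).

## Data-preparation arithmetic

Unit-value prices are pooled ratios Σ expenditure / Σ quantity per source
category (not means of per-record ratios); food-category prices are
quantity-weighted means of matched source prices, and a food with no
priced source is flagged unpriced rather than silently zeroed. Category
nutrient densities are consumption-share weighted means of item densities,
hence always inside the elementwise convex hull of the items. Income is
equivalized by the OECD scale (1.0 first adult / 0.7 further adults /
0.5 minors); quantile strata use empirical quantile cut points with ties
assigned to the lower stratum, which makes assignments deterministic and
invariant to monotone rescaling. Habit percentiles use linear (type-7)
interpolation between order statistics on unweighted samples; survey
weights are out of scope, and the quantile definition is a documented
choice rather than a published fact.

## Decomposition

For unit values `v` (price or GHGE intensity) and main category C with
quantity `Q_C = Σ_{i∈C} x_i`, value `V_C = Σ_{i∈C} v_i x_i` and baseline
mean unit value `v̄_C⁰ = V_C⁰/Q_C⁰`:

```
inter_C = v̄_C⁰ · (Q_C¹ − Q_C⁰)      intra_C = V_C¹ − v̄_C⁰ · Q_C¹
```

so `intra + inter = ΔV_C` holds to machine precision per category and in
the grand total. This is the Laspeyres-type convention (inter valued at
the baseline category mix, intra as the residual re-composition at final
quantity) — the simplest exact two-term additive scheme; a Paasche-type
variant (final-weighted) would differ per category but not in the total. A
category with zero baseline quantity has no mean unit value; its whole
change is booked as inter. If all members of a category share one unit
value the intra term vanishes identically.

## Synthetic data generator

The generator stands in for restricted survey, budget-survey and
life-cycle-assessment inputs. What it emulates:

* **Structure**: 74 foods in 16 main categories (counts per category follow
  the reporting classification; scaled by largest remainder for other
  sizes); 61 bounded nutrients split 30 macronutrients (including %E-bounded
  protein/fat/carbohydrate/alcohol and six indispensable amino acids),
  13 vitamins, 18 minerals including iron.
* **Prices and emissions**: category-level means with ±25 % lognormal
  jitter; animal-source categories carry a 2× price and 5× GHGE multiplier,
  beef an extra 3× GHGE and 1.5× price ruminant premium (beef is both the
  most carbon-intensive and the dearest common protein source — without the
  price premium a lucky draw can make beef the cheapest protein and push
  the minimum-cost diet's emissions toward the cap, a regime real price
  data do not support). The resulting baseline attributes roughly match
  the reported pattern: meat and dairy together carry ~60 % of baseline
  GHGE.
* **Nutrient densities** are tied to energy density with category
  affinities (vitamins concentrated in fruits/vegetables, minerals in
  vegetables/dairy/cereals, iron in meat/fish plus substantial non-haem
  iron in cereals and legumes, amino acids proportional to protein), so
  isocaloric substitutions move nutrient totals smoothly and low-emission
  nutrient sourcing exists, as it does in real food-composition data.
* **Baseline diets**: strictly positive, scaled to hit the target energy
  exactly (7311 kJ/d female, ×1.28 male, matching the reported sex gap),
  and adjusted to satisfy the dairy–beef row with a 10 % margin before the
  isocaloric rescale (uniform rescaling preserves the row).
* **Habit bounds**: per food, 780 person-level draws from a lognormal with
  the baseline as mean and σ = 1.0 (right-skewed, typical of intake data),
  zero-inflated (π = 0.2) for the 20 % least-consumed foods so that P10 may
  be 0 — habit bounds can permit exclusion of rarely eaten foods. Sampled
  percentiles are widened to include the baseline when necessary.
* **Nutrient bounds**: lower = 0.8 ×, upper = 1.5 × the baseline-implied
  intake (%E bounds built the same way on the baseline energy share, capped
  at 100; alcohol gets an upper bound only — recommendations never require
  alcohol). Amino-acid floors use 0.55 so that the builder's 1.24 safety
  margin still leaves the baseline feasible. With these defaults the
  baseline solves the health-only problem exactly — a deliberate
  feasibility-by-construction stand-in for a full recommendation table,
  which can instead be supplied via `bounds.csv`.
* **Stress mode** raises the floors of four randomly chosen
  vitamins/minerals 10 % above baseline intake, making the baseline
  infeasible and forcing genuine optimization. The stressed floors are
  then repaired constructively: the tightest system (−50 % cap with habit
  box) is checked for a feasible point and offending floors are pulled
  halfway back toward baseline until it is nonempty, so the generator
  honours its feasibility contract on every seed while stressing as hard
  as each instance allows.

What the generator does **not** emulate: real Finnish prices, intakes or
LCA coefficients; survey weighting; correlated consumption across foods;
seasonal or meal-level structure; measurement error in recalls. Passing
tests on synthetic data therefore demonstrate the correctness of the
optimization, decomposition and reporting machinery and the qualitative
regime (cheap diets are low-emission; tightening the cap lowers cost), not
the published Finnish point estimates — those are checked separately
against the packaged result tables, which are inputs, not model output.

## Problem sizes used in the test and acceptance runs

Full-size instances (74 foods, 61 nutrients) are used for the seeded
contract suites (20 seeds for baseline recovery and for cap-tightness
monotonicity); oracle-equivalence checks run on tiny random instances
(≤ 3 foods for LP vertex enumeration over 100 instances, ≤ 6 foods for
exact KKT active-set enumeration over 50 instances) where exhaustive
enumeration is exact; the CLI/pipeline round-trip tests use a reduced
24-food universe. These sizes are the package's own choice of test design:
enumeration oracles must stay exhaustive, and the contract suites exercise
the default study conditions.

## Known limitations

* The QP back-ends plus polish deliver objectives within ~1e-9 of the
  exact optimum on enumerable instances, but the polish accepts only
  feasible improvements; on a pathologically degenerate active set it
  falls back to the iterate.
* The one-at-a-time infeasibility diagnosis cannot isolate conflicts that
  require relaxing two families jointly; it then reports that no single
  family explains the infeasibility.
* Small universes (a few foods per category) can make the −50 % cap
  genuinely incompatible with the baseline-pinned female iron floor; such
  cells are recorded as infeasible with a diagnosis rather than repaired,
  since the conflict is structural, not numerical.
* LP solution diets are reported unthresholded; trace quantities (e.g.
  0.3 g/d) count as consumed in diversity counts, matching the worked
  example's convention.
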