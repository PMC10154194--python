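# Methods

`circfood` models a self-sufficient, multi-country food system as a linear
program and asks two questions of it: *what is the least agricultural land
that can feed the population a diet satisfying the chosen constraints?* and
*how many people could the available land feed?* Greenhouse-gas emissions
are accounted after the fact from the solved system; they never enter the
objective. This note records the model, its assumptions, the parameters
that matter, what the synthetic data do and do not emulate, and the
numerical choices.

## The optimization model

**Decision variables** (all nonnegative): crop area per (crop, zone); grass
harvest/grazing area per (zone, grassland type); producing-animal units per
(system, country); feed allocations per (feed item, system, country); food
flows per (commodity, origin, destination); delivered food per (commodity,
country); fertilizer N applied per (source, crop, zone) with artificial N
and P as separate variables; waste routed to feed and to compost per
country; fish landings per (stock, country); and, in population-maximizing
mode, a single population multiplier *m*.

**Constraint families.**

- *Nutrition*: per country, intake of each bounded nutrient (42 tracked:
  fresh weight, energy, macronutrients, fat types, minerals, vitamins,
  essential amino acids) must lie within its per-capita bounds. Intake is
  delivered mass reduced by the consumption-stage waste fraction.
- *Food groups*: per-capita intake guardrails per group (e.g. red meat at
  most 28 g/day, vegetables 200–600 g/day); the grains bound is a maximum
  share (60%) of energy intake and is scale-free.
- *Protein matching* (supply-side scenarios): delivered protein per
  (country, food group) must reach the instance's current supply. Matching
  is a minimum (≥), not an equality — scenarios may over-deliver protein
  in a group. This is one of two mutually exclusive diet modes.
- *Land, rotation, suitability*: crop areas are bounded by zone cropland,
  by the rotation cap (a 1-in-k rotation becomes a static annual area share
  of 1/k of cropland), and by current-acreage caps for declared minor
  crops; a crop with no yield in a zone cannot be grown there.
- *Mass balance*: harvested crop mass (after post-harvest loss) splits into
  processing and whole-crop feed; processing yields the main food product
  and by-products via technical conversion factors; food available for
  shipment is the main product after processing- and distribution-stage
  losses; deliveries cannot exceed inflows.
- *Feed*: per (system, country), summed feed energy and digestible protein
  must cover the herd requirement — producing units plus parent and
  reproduction stock coupled by fixed ratios — within the herd's dry-matter
  intake capacity. Species legality is structural: illegal (feed, species)
  pairs have no variables, so food waste can never reach ruminants.
- *Fertilizer*: per (crop, zone), delivered N must cover the N removed in
  harvest plus aboveground residues, and applied P must cover P removal
  times 1.125 (the 12.5% unavoidable loss). Each organic source delivers
  N and P jointly at its fixed N:P ratio; organic nutrients are fully
  plant-available (long-term equilibrium assumption). Source availability
  per country ties manure to excreted N from housed feeding, compost to
  composted waste N, excreta to the sludge stream, and by-product
  fertilizer to by-product mass.
- *Residual streams*: waste to feed is capped at 35% of the consumption
  waste pool, waste use at the pool itself; waste and grass are usable only
  in the country where they arise (again structural: no cross-border
  variables exist).
- *Fisheries*: landings per stock and country are capped at the maximum
  sustainable yield share.
- *Transport*: cross-border flows are charged distance × emission factor
  and capped at 1,500 kg CO2e per capita per year per destination country.
  This is the only emission term that constrains the optimization.

**Delivered-N crediting.** The removal-based N requirement with losses,
`requirement = removal × (1 + volatilization + leaching)`, is well defined
for a single fertilizer source but ambiguous for a mix. The balance is
therefore written as `Σ_source applied × 1/(1 + losses_source) ≥ removal`,
which reduces to the single-source formula and stays linear for mixes.
Loss fractions default to 0.10 volatilization for synthetic N, 0.21 for
organic sources, and 0.24 leaching in wet climates (0 in dry), all
configurable per instance. `fertilizer_requirement` also exposes the
divisor reading (`removal / (1 − loss)`) and a residue-offset mode behind
flags; the optimizer uses the defaults.

**Population scaling.** In max-population mode every per-capita constraint
is written with demand proportional to *m* (e.g. `intake ≥ min × pop × m`),
which keeps the problem linear in (diet quantities, *m*) because diet
variables are totals, not per-capita amounts.

**Objectives.** `min_agricultural_land` minimizes cropped plus grazed/
harvested grassland area. `max_population_fed` maximizes *m*
lexicographically: stage one maximizes *m* alone; stage two fixes *m* at
its optimum and minimizes land, so the reported land use is the least land
that feeds the maximal population (without the second stage, land is
undetermined among alternative optima). `calibrate_baseline` fixes crop
areas to the instance's current areas and minimizes the sum of relative
deviations of per-food-group protein supply from current supply,
linearized with positive/negative slack variables.

**Grazing and grassland.** Grass is standing biomass harvested or grazed
from the zone's grassland endowment; it is not fertilized in the model, so
grassland N2O arises only from grazing deposition. Temporary grassland is
treated as harvested (manure goes to the management system); permanent
pasture and rangeland are grazed, and the grazing share used to split
manure is the permanent-grass share of the ration's nitrogen — a linear
expression, not a free variable.

## GHG accounting

Computed post hoc from the solved system, per source category and gas,
aggregated with 100-yr GWPs (biogenic CH4 × 28, N2O × 265; N→N2O by
44/28):

- enteric CH4 = gross energy intake × Ym/100 / 55.65 (ruminants);
- manure-management CH4 = VS × MCF × B0 × 0.67, where VS is the
  indigestible organic matter of the realized ration (ash-corrected);
  grazed VS uses a pasture MCF of 0.01;
- manure N2O (direct + volatilization-indirect) on managed N; grassland
  N2O on grazing-deposited N;
- aquaculture N2O = 1.8% of non-retained N;
- soil N2O per fertilizer source and climate moisture (direct + indirect
  via volatilized and leached N), plus an area-based term on drained
  organic (peat) soils;
- compost N2O from composted N (EF 0.01 kg N2O-N/kg N) and CH4 from
  compost carbon derived via a C:N ratio of 15 (2.5% of C as CH4) — both
  EFs are configuration defaults, logged in the instance;
- artificial-fertilizer production CO2e (5 kg/kg N, 2 kg/kg P defaults)
  and transport CO2e (0.1 kg/t-km default).

CH4 from rice and CO2 from soils and cropping are excluded. Inventory
categories are disjoint and exhaustive: the total equals the category sum
exactly. No minimum-emission objective is offered; emissions are
deliberately accounting-only.

## Synthetic instances

The generator builds instances whose *structure* matches what the model
needs, without claiming distributional fidelity to any real region:

- **Zones and yields**: zones carry the four land types, a climate class
  (moisture drives emission and leaching factors) and a soil class (organic
  = peat). Yields are group-level means times lognormal zone multipliers
  (σ = 0.3 by default): strictly positive and right-skewed like real yield
  data.
- **Compositions**: per-food-group anchor tables with ±10% lognormal
  jitter; amino acids follow fixed shares of protein (plant vs animal
  profiles). Vitamin B12, cholesterol, DHA and EPA are zero in all plant
  foods and positive in all animal-source foods, so healthy-diet scenarios
  genuinely require animal-source food.
- **Residual streams**: stage-wise waste fractions drawn in (0.02, 0.22)
  per stage (every consumption pool strictly positive); technical
  conversion factors per crop group (e.g. milling 0.75 main + 0.22 bran).
- **Animal systems**: species parameter table (dairy, pig, broiler, layer,
  beef, salmon, tilapia; productivity levels scale requirements by +15%/
  +30%) with herd coupling, retention fractions, manure-management
  parameters and Ym for ruminants. The default four systems are dairy,
  pig, broiler and layer.
- **Current baseline**: a current supply profile (protein-heavy, red meat
  and dairy above the healthy guardrails) is translated into the crop,
  fodder and grass production needed to deliver it through the waste and
  processing chains, using fixed per-species ration recipes whose energy,
  protein and intake arithmetic is checked in code. Zone cropland is set
  to 2.5× the current cultivated area and grassland to 1.6× baseline
  grazing needs, so the fixed-area calibration scenario is feasible by
  construction and the optimizing scenarios have slack land.
- **Nutrient bounds**: minima and maxima are anchored to the nutrient
  vector of a reference healthy intake within the food-group guardrails
  (minima at 50–80% of the reference, energy maximum at 130%), which makes
  the healthy-diet scenarios feasible without real dietary reference data.

What passing tests therefore show: the *mechanics* — balances, legality,
caps, linearity, optimality — are correct on internally consistent data.
What they do not show: that the generator's magnitudes match any real
region's; headline results on synthetic instances (e.g. land −79%,
per-capita CO2e −66%, +117% population on the default seed) are properties
of the synthetic conditions, not predictions.

Two special generators support verification: a known-optimum instance in
which one crop strictly dominates the alternative in every bounded
nutrient per hectare (same composition, double yield), making the optimum
a one-line closed form; and tiny crop-only instances on which exhaustive
grid search over per-capita diets reproduces the optimum independently of
the LP.

## Numerical choices

- Solver: HiGHS through `scipy.optimize.linprog`, sparse matrices,
  default tolerances (primal/dual ~1e-7). Variable order is fixed by
  sorted identifiers, so repeated solves are bit-identical.
- Degenerate optima: vanishing tie-break costs (1e-10 per ton-km on
  cross-border flows; 1e-9 per kg artificial N/P so organic sources are
  preferred among equivalent fertilizer mixes; both ≲1e-8 of the
  objective). Tie-break costs below the solver's dual tolerance must never
  be the *only* competition to a primary cost term — max-population mode
  therefore uses the two-stage lexicographic solve described above.
- Infeasibility: reported as a structured error listing the constraint
  families whose individual removal restores feasibility.
- Bounds are inclusive everywhere (closed half-spaces); validators use
  relative tolerances (1e-6, scaled) when re-checking solver output.
- Degenerate inputs: zero areas, empty diets, zero targets and empty
  inventories all return exact zeros rather than errors; fishery quotas
  above MSY are clipped with a logged warning, as specified.

## Limitations

- Only food commodities cross borders; by-products and fodder are used in
  the country of production (waste and grass are required to be, the rest
  is a simplification).
- Feed quality is tracked as metabolizable energy and digestible protein;
  the schema admits more nutrients but the default instances do not
  populate them.
- Grassland is unfertilized; grass growth does not respond to deposition.
- Wild-fish composition uses the first stock's values for the pooled
  commodity.
- The manure N:P delivery ratio is a source-class constant rather than
  emerging from each herd's excretion, consistent with the fixed-ratio
  assumption for organic fertilizers.
- No soil organic-matter constraints, no crop sequence ordering, no
  land-use-change CO2, no bioavailability interactions.
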