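"""Scenario presets, scenario reports, percent changes, brute-force oracle.

Four standard configurations mirror a baseline-plus-circularity study design:

* **agribase** — calibration baseline: crop areas fixed to current values,
  the objective minimizes the deviation of per-food-group protein supply
  from the current supply; artificial fertilizer capped at current use.
* **ciragri** — supply-side circularity: minimize agricultural land while
  meeting current protein supply per country and food group; waste and
  by-product recycling enabled.
* **cirhealth** — circularity plus a healthy diet: minimize land under
  per-nutrient intake bounds and food-group guardrails.
* **cirpop** — healthy circular diet, maximize the population fed from the
  available land.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instance import FoodSystemInstance, Solution
from .model import (
    InfeasibleProblemError,
    ProblemSpec,
    ScenarioConfig,
    build_problem,
    solve,
    verify_solution,
)
from .nutrients import ANIMAL_GROUPS, NUTRIENTS


def agribase() -> ScenarioConfig:
    return ScenarioConfig(
        name="agribase",
        diet_mode="current_protein_by_food_group",
        objective="calibrate_baseline",
        fixed_current_areas=True,
        waste_to_feed_allowed=False,
        byproducts_to_fertilizer_allowed=False,
    )


def ciragri() -> ScenarioConfig:
    return ScenarioConfig(
        name="ciragri",
        diet_mode="current_protein_by_food_group",
        objective="min_agricultural_land",
    )


def cirhealth() -> ScenarioConfig:
    return ScenarioConfig(
        name="cirhealth",
        diet_mode="efsa_plus_eat_lancet",
        objective="min_agricultural_land",
    )


def cirpop() -> ScenarioConfig:
    return ScenarioConfig(
        name="cirpop",
        diet_mode="efsa_plus_eat_lancet",
        objective="max_population_fed",
    )


PRESETS = {"agribase": agribase, "ciragri": ciragri,
           "cirhealth": cirhealth, "cirpop": cirpop}


def percent_change(baseline: float, scenario: float) -> int:
    """Signed percent change, rounded to the nearest integer.

    A land drop from 172 to 50 Mha is -71; identical values give 0.
    """
    if baseline == 0:
        raise ZeroDivisionError("baseline must be nonzero for a percent change")
    return int(round(100.0 * (scenario - baseline) / baseline))


@dataclass
class ScenarioReport:
    """Machine-readable summary of one scenario run."""

    scenario: str
    solution: Solution
    land_by_group: pd.DataFrame       # crop group x land (ha)
    land_by_type: pd.DataFrame        # cropland vs grassland (ha)
    ghg_by_category: pd.DataFrame     # category -> kg CO2e/yr
    np_by_source: pd.DataFrame        # fertilizer source x (N, P) kg/yr
    animal_protein: pd.DataFrame      # species -> t protein/yr
    nutrient_intake: pd.DataFrame     # nutrient x (intake, min, max), pop-weighted
    population_fed: float = 0.0
    total_land_ha: float = 0.0
    total_co2e_kg: float = 0.0
    co2e_per_capita_kg: float = 0.0
    violations: list[str] = field(default_factory=list)


def run_scenario(inst: FoodSystemInstance, scen: ScenarioConfig,
                 verify: bool = True) -> ScenarioReport:
    """Build, solve and summarize one scenario on an instance."""
    spec = build_problem(inst, scen)
    sol = solve(spec)

    land_rows: dict[str, float] = {}
    for (cid, _z), a in sol.area.items():
        g = inst.crops[cid].food_group
        land_rows[g] = land_rows.get(g, 0.0) + a
    land_by_group = pd.DataFrame(
        sorted(land_rows.items()), columns=["crop_group", "area_ha"])

    cropland = sum(sol.area.values())
    grassland = sum(sol.grass_area.values())
    land_by_type = pd.DataFrame(
        [["cropland", cropland], ["grassland", grassland]],
        columns=["land_type", "area_ha"])

    inv = sol.ghg
    ghg_rows = [[cat, inv.by_category_co2e(cat)]
                for cat in sorted({c for (c, g) in inv.entries})] if inv else []
    ghg_by_category = pd.DataFrame(ghg_rows, columns=["category", "kg_co2e"])

    np_rows: dict[str, list[float]] = {}
    for (src, _c, _z), (n, p) in sol.fertilizer.items():
        acc = np_rows.setdefault(src, [0.0, 0.0])
        acc[0] += n
        acc[1] += p
    np_by_source = pd.DataFrame(
        [[s, v[0], v[1]] for s, v in sorted(np_rows.items())],
        columns=["source", "n_kg", "p_kg"])

    prot_rows: dict[str, float] = {}
    for (sid, _k), units in sol.animals.items():
        s = inst.animal_systems[sid]
        t_prod = units * s.output_t_per_unit
        prot = s.product_composition.get("protein", 0.0) * 1e6 * t_prod  # g->t? per g
        prot_rows[s.species] = prot_rows.get(s.species, 0.0) + prot / 1e6
    animal_protein = pd.DataFrame(
        sorted(prot_rows.items()), columns=["species", "protein_t"])

    # population-weighted nutrient intake vs bounds
    total_pop = inst.total_population() * sol.population_multiplier
    intake_rows = []
    for nid in NUTRIENTS:
        spec_n = inst.nutrient_specs[nid]
        weighted = 0.0
        for k in inst.countries:
            pop = inst.population_by_country[k] * sol.population_multiplier
            intake_k = sum(
                sol.diet.get((f, k), 0.0)
                * inst.food_composition_of(f).get(nid, 0.0)
                for f in inst.food_ids())
            weighted += intake_k * pop
        intake_rows.append([nid, weighted / total_pop if total_pop else 0.0,
                            spec_n.min_per_capita_day, spec_n.max_per_capita_day])
    nutrient_intake = pd.DataFrame(
        intake_rows, columns=["nutrient", "intake", "min", "max"])

    total_co2e = inv.total_co2e() if inv else 0.0
    report = ScenarioReport(
        scenario=scen.name,
        solution=sol,
        land_by_group=land_by_group,
        land_by_type=land_by_type,
        ghg_by_category=ghg_by_category,
        np_by_source=np_by_source,
        animal_protein=animal_protein,
        nutrient_intake=nutrient_intake,
        population_fed=sol.population_fed,
        total_land_ha=sol.total_land_ha(),
        total_co2e_kg=total_co2e,
        co2e_per_capita_kg=(total_co2e / sol.population_fed
                            if sol.population_fed else 0.0),
    )
    if verify:
        report.violations = verify_solution(inst, scen, sol)
    return report


# ---------------------------------------------------------------------------
# brute-force oracle for tiny crop-only instances
# ---------------------------------------------------------------------------

class OracleError(RuntimeError):
    pass


def brute_force_optimum(inst: FoodSystemInstance, scen: ScenarioConfig,
                        grid_g_day: float = 1.0,
                        max_g_day: float = 2000.0) -> float | None:
    """Grid-search the land-minimizing diet on a tiny crop-only instance.

    Exhaustively enumerates per-capita diets on a grid (step ``grid_g_day``
    grams/day per food), checks the dietary constraint families directly, and
    converts the best feasible diet to land via each crop's yield chain. The
    search is independent of the LP path: it never calls the solver.

    Requires a single-country, single-zone, animal-free instance with slack
    rotation caps (the regime where land is separable per crop). Returns the
    minimum land (ha) over feasible grid points, or ``None`` if no grid point
    is feasible.
    """
    if len(inst.countries) != 1 or len(inst.zones) != 1:
        raise OracleError("oracle requires one country and one zone")
    if inst.animal_systems or inst.fish_stocks:
        raise OracleError("oracle handles crop-only instances")
    if scen.diet_mode != "efsa_plus_eat_lancet":
        raise OracleError("oracle supports the nutrient-bound diet mode")

    k = inst.countries[0]
    zid = next(iter(inst.zones))
    pop = inst.population_by_country[k]
    foods = [c for c in sorted(inst.crops) if inst.crops[c].is_food_crop]
    if len(foods) > 3:
        raise OracleError("oracle limited to <= 3 crops")

    rp = inst.residual_params
    land_per_g_day = []
    comp = []
    cons_keep = []
    for f in foods:
        crop = inst.crops[f]
        fr = rp.stage_fracs_for(f)
        keep = 1.0
        for st in ("post_harvest", "processing", "distribution"):
            keep *= 1.0 - fr.get(st, 0.0)
        main = float(rp.tcf.get(f, {}).get("main_fraction", 1.0))
        y = crop.yield_by_zone[zid]
        # t crop / yr per g/day delivered, then ha per g/day delivered
        t_per_gday = pop * 365.0 / 1e6
        land_per_g_day.append(t_per_gday / (keep * main * y))
        comp.append(crop.food_composition)
        cons_keep.append(1.0 - fr.get("consumption", 0.0))

    steps = [np.arange(0.0, max_g_day + grid_g_day / 2, grid_g_day)
             for _ in foods]
    mesh = np.meshgrid(*steps, indexing="ij")
    dlv = np.stack([m.ravel() for m in mesh], axis=1)  # delivered g/day
    intake = dlv * np.array(cons_keep)

    feasible = np.ones(len(dlv), dtype=bool)
    for nid in NUTRIENTS:
        spec = inst.nutrient_specs[nid]
        conc = np.array([c.get(nid, 0.0) for c in comp])
        vals = intake @ conc
        if spec.min_per_capita_day is not None and spec.min_per_capita_day > 0:
            feasible &= vals >= spec.min_per_capita_day - 1e-9
        if spec.max_per_capita_day is not None:
            feasible &= vals <= spec.max_per_capita_day + 1e-9
    group_of = [inst.crops[f].food_group for f in foods]
    energy = np.array([c.get("energy", 0.0) for c in comp])
    tot_energy = intake @ energy
    for gid, bound in sorted(inst.food_group_bounds.items()):
        members = np.array([g == gid for g in group_of])
        if not members.any():
            if bound.min_g_day > 0:
                feasible &= False
            continue
        if bound.max_energy_share is not None:
            ge = (intake * energy) @ members
            feasible &= ge <= bound.max_energy_share * tot_energy + 1e-9
            continue
        grams = intake @ members
        feasible &= grams >= bound.min_g_day - 1e-9
        if bound.max_g_day is not None:
            feasible &= grams <= bound.max_g_day + 1e-9

    if not feasible.any():
        return None
    land = dlv @ np.array(land_per_g_day)
    return float(land[feasible].min())


def solve_or_none(inst: FoodSystemInstance, scen: ScenarioConfig
                  ) -> Solution | None:
    """Solve a scenario, returning None instead of raising on infeasibility."""
    try:
        return solve(build_problem(inst, scen))
    except InfeasibleProblemError:
        return None
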