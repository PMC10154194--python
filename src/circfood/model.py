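"""Scenario configuration, LP assembly, solving and solution verification.

The food-system design problem is a linear program. Decision variables are
crop areas per (crop, zone), grass harvest areas, producing-animal units per
(system, country), feed allocations, commodity flows between countries,
fertilizer applications per (source, crop, zone), delivered food quantities
and - in population-maximizing mode - a population multiplier. Constraint
families cover nutrition, food-group guardrails, protein-supply matching,
land, rotation and suitability caps, feed balances with species legality,
N/P fertilizer balances, residual-stream availability, fishery MSY caps,
in-country-use rules for waste and grass, and a per-capita transport CO2e
cap. Emissions are computed post hoc from the solved system; only the
transport cap constrains the optimization.

The LP is solved with HiGHS via ``scipy.optimize.linprog``; variable order
is fixed (sorted identifiers) and a vanishing secondary cost on cross-border
flows breaks ties among degenerate optima, so repeated solves are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from . import ghg as ghg_mod
from .animals import ration_volatile_solids
from .cropping import delivered_n_fraction, rotation_share, suitable_crops
from .instance import (
    FERTILIZER_SOURCES,
    GRASS_TYPES,
    FoodSystemInstance,
    Solution,
    TRACKED_FEED_NUTRIENTS,
)
from .nutrients import FODDER_GROUP, NUTRIENTS, RUMINANT_SPECIES

DIET_MODES = ("current_protein_by_food_group", "efsa_plus_eat_lancet")
OBJECTIVES = ("min_agricultural_land", "max_population_fed", "calibrate_baseline")

ORGANIC_SOURCES = tuple(s for s in FERTILIZER_SOURCES if s != "artificial")

#: Grazing happens on permanent grassland; temporary grass is harvested.
GRAZED_GRASS_TYPES = ("permanent_pasture", "rangeland")

_DAYS = 365.0
_EPS_FLOW = 1e-10  # vanishing tie-break cost per ton-km on cross-border flows
_EPS_ART = 1e-9    # vanishing cost per kg artificial N/P: prefer organics
#                    among otherwise-equivalent fertilizer mixes


@dataclass(frozen=True)
class ScenarioConfig:
    """Switches defining one scenario run."""

    name: str
    diet_mode: str
    objective: str
    artificial_fertilizer_allowed: bool = True
    waste_to_feed_allowed: bool = True
    waste_to_compost_allowed: bool = True
    byproducts_to_feed_allowed: bool = True
    byproducts_to_fertilizer_allowed: bool = True
    trade_allowed_between_countries: bool = True
    transport_co2e_cap_per_capita: float = 1500.0
    fixed_current_areas: bool = False
    artificial_fertilizer_cap_t: float | None = None

    def __post_init__(self) -> None:
        if self.diet_mode not in DIET_MODES:
            raise ValueError(f"unknown diet mode {self.diet_mode!r}")
        if self.objective not in OBJECTIVES:
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.objective == "calibrate_baseline" and not self.fixed_current_areas:
            raise ValueError("baseline calibration requires fixed current areas")


class InfeasibleProblemError(RuntimeError):
    """Solve failed; carries a structured report of implicated families."""

    def __init__(self, message: str, families: list[str]):
        super().__init__(message)
        self.families = families


@dataclass
class ProblemSpec:
    """An assembled LP plus the metadata needed to extract a Solution."""

    instance: FoodSystemInstance
    scenario: ScenarioConfig
    var_keys: list[tuple]
    bounds: list[tuple[float, float | None]]
    cost: np.ndarray
    a_ub: sparse.csr_matrix
    b_ub: np.ndarray
    fam_ub: list[str]
    a_eq: sparse.csr_matrix
    b_eq: np.ndarray
    fam_eq: list[str]
    families_present: tuple[str, ...]
    context: dict[str, Any] = field(default_factory=dict)

    @property
    def n_vars(self) -> int:
        return len(self.var_keys)

    @property
    def n_constraints(self) -> int:
        return len(self.fam_ub) + len(self.fam_eq)


class _Builder:
    def __init__(self) -> None:
        self.index: dict[tuple, int] = {}
        self.keys: list[tuple] = []
        self.lb: list[float] = []
        self.ub: list[float | None] = []
        self.cost: list[float] = []
        self.rows_ub: list[dict[int, float]] = []
        self.rhs_ub: list[float] = []
        self.fam_ub: list[str] = []
        self.rows_eq: list[dict[int, float]] = []
        self.rhs_eq: list[float] = []
        self.fam_eq: list[str] = []
        self.families: set[str] = set()

    def var(self, key: tuple, lb: float = 0.0, ub: float | None = None,
            cost: float = 0.0) -> int:
        if key in self.index:
            return self.index[key]
        i = len(self.keys)
        self.index[key] = i
        self.keys.append(key)
        self.lb.append(lb)
        self.ub.append(ub)
        self.cost.append(cost)
        return i

    def has(self, key: tuple) -> bool:
        return key in self.index

    def add_cost(self, key: tuple, c: float) -> None:
        self.cost[self.index[key]] += c

    def _row(self, coefs: Mapping[tuple, float]) -> dict[int, float]:
        return {self.index[k]: float(v) for k, v in coefs.items() if v != 0.0}

    def le(self, coefs: Mapping[tuple, float], rhs: float, family: str) -> None:
        self.rows_ub.append(self._row(coefs))
        self.rhs_ub.append(float(rhs))
        self.fam_ub.append(family)
        self.families.add(family)

    def ge(self, coefs: Mapping[tuple, float], rhs: float, family: str) -> None:
        self.le({k: -v for k, v in coefs.items()}, -rhs, family)

    def eq(self, coefs: Mapping[tuple, float], rhs: float, family: str) -> None:
        self.rows_eq.append(self._row(coefs))
        self.rhs_eq.append(float(rhs))
        self.fam_eq.append(family)
        self.families.add(family)

    def mark(self, family: str) -> None:
        self.families.add(family)

    def matrix(self, rows: list[dict[int, float]]) -> sparse.csr_matrix:
        data, ri, ci = [], [], []
        for r, row in enumerate(rows):
            for c, v in row.items():
                ri.append(r)
                ci.append(c)
                data.append(v)
        return sparse.csr_matrix(
            (data, (ri, ci)), shape=(len(rows), len(self.keys)))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _chain(inst: FoodSystemInstance, food: str) -> dict[str, float]:
    fr = inst.residual_params.stage_fracs_for(food)
    return {
        "ph": float(fr.get("post_harvest", 0.0)),
        "proc": float(fr.get("processing", 0.0)),
        "dist": float(fr.get("distribution", 0.0)),
        "cons": float(fr.get("consumption", 0.0)),
    }


def _tcf_entry(inst: FoodSystemInstance, crop_id: str) -> dict[str, Any]:
    return inst.residual_params.tcf.get(
        crop_id, {"main_fraction": 1.0, "byproducts": {}})


def build_problem(inst: FoodSystemInstance, scen: ScenarioConfig) -> ProblemSpec:
    """Assemble the scenario LP for an instance.

    Raises ``ValueError`` on configuration/instance mismatches (e.g. a
    protein-matching diet mode without current-supply data).
    """
    if (scen.diet_mode == "current_protein_by_food_group"
            and not inst.current_supply_protein):
        raise ValueError(
            "diet mode matches current protein supply but the instance "
            "carries no current_supply_protein data")
    if scen.fixed_current_areas and not inst.current_areas:
        raise ValueError("fixed_current_areas requires current_areas data")

    b = _Builder()
    rp = inst.residual_params
    ec = inst.emission_constants
    countries = inst.countries
    maxpop = scen.objective == "max_population_fed"
    baseline = scen.objective == "calibrate_baseline"
    foods = inst.food_ids()
    chain = {f: _chain(inst, f) for f in foods}
    comp = {f: inst.food_composition_of(f) for f in foods}
    group_of = {f: inst.food_group_of(f) for f in foods}

    mult = b.var(("mult",), lb=0.0) if maxpop else None

    def percap_ge(coefs: Mapping[tuple, float], req: float, family: str) -> None:
        """Per-capita requirement: sum(coefs) >= req (x mult if present)."""
        row = dict(coefs)
        if mult is not None:
            row[("mult",)] = row.get(("mult",), 0.0) - req
            b.ge(row, 0.0, family)
        else:
            b.ge(row, req, family)

    def percap_le(coefs: Mapping[tuple, float], cap: float, family: str) -> None:
        """Per-capita cap: sum(coefs) <= cap (x mult if present)."""
        row = dict(coefs)
        if mult is not None:
            row[("mult",)] = row.get(("mult",), 0.0) - cap
            b.le(row, 0.0, family)
        else:
            b.le(row, cap, family)

    # -- areas, rotation and suitability caps --------------------------------
    land_cost = 1.0 if scen.objective != "calibrate_baseline" else 0.0
    pairs: list[tuple[str, str]] = []
    for zid in sorted(inst.zones):
        zone = inst.zones[zid]
        caps = suitable_crops(zone, inst)
        for cid, cap in sorted(caps.items()):
            if scen.fixed_current_areas:
                cur = float(inst.current_areas.get(cid, {}).get(zid, 0.0))
                b.var(("area", cid, zid), lb=cur, ub=cur, cost=land_cost)
            else:
                b.var(("area", cid, zid), lb=0.0, ub=cap, cost=land_cost)
            pairs.append((cid, zid))
        b.mark("rotation")
        b.mark("suitability")
        # grass areas, bounded by the zone's grassland endowment
        for gt in GRASS_TYPES:
            avail = zone.area_by_land_type.get(gt, 0.0)
            gy = inst.grass_yield.get(zid, {}).get(gt, 0.0)
            if avail > 0 and gy > 0 and gt in inst.grass_feed_map:
                b.var(("grass", zid, gt), lb=0.0, ub=avail, cost=land_cost)
        # cropland exhaustion per zone
        if caps and not scen.fixed_current_areas:
            b.le({("area", cid, zid): 1.0 for cid in caps},
                 zone.cropland_ha(), "land")
        b.mark("land")

    # -- crop harvest and use ------------------------------------------------
    for cid in sorted(inst.crops):
        crop = inst.crops[cid]
        for k in countries:
            zs = [z for z in inst.zones_in(k) if z in crop.yield_by_zone
                  and b.has(("area", cid, z))]
            if not zs:
                continue
            ph = _chain(inst, cid)["ph"] if crop.is_food_crop else 0.0
            use_row: dict[tuple, float] = {}
            if crop.is_food_crop:
                use_row[("proc", cid, k)] = 1.0
                b.var(("proc", cid, k))
            if crop.feed_value_id is not None:
                use_row[("cfeed", cid, k)] = 1.0
                b.var(("cfeed", cid, k))
            if not use_row:
                continue
            for z in zs:
                use_row[("area", cid, z)] = -(1.0 - ph) * crop.yield_by_zone[z]
            b.le(use_row, 0.0, "mass_balance")

    # -- food availability, flows and delivery -------------------------------
    for f in foods:
        ch = chain[f]
        post = (1.0 - ch["proc"]) * (1.0 - ch["dist"])
        for ko in countries:
            avail_row: dict[tuple, float] = {}
            if f in inst.crops:
                if b.has(("proc", f, ko)):
                    main = float(_tcf_entry(inst, f).get("main_fraction", 1.0))
                    avail_row[("proc", f, ko)] = -main * post
            elif f == "wild_fish":
                for st in sorted(inst.fish_stocks):
                    stk = inst.fish_stocks[st]
                    cap = float(stk.msy_cap_t.get(ko, 0.0))
                    if cap > 0:
                        b.var(("landing", st, ko), ub=cap)
                        avail_row[("landing", st, ko)] = (
                            -stk.edible_frac * (1.0 - ch["ph"]) * post)
                b.mark("fishery")
            else:
                for sid in sorted(inst.animal_systems):
                    s = inst.animal_systems[sid]
                    if s.food_id == f:
                        b.var(("an", sid, ko))
                        avail_row[("an", sid, ko)] = (
                            -s.output_t_per_unit * (1.0 - ch["ph"]) * post)
            dests = countries if scen.trade_allowed_between_countries else [ko]
            for kd in dests:
                b.var(("flow", f, ko, kd))
                avail_row[("flow", f, ko, kd)] = avail_row.get(
                    ("flow", f, ko, kd), 0.0) + 1.0
                if ko != kd:
                    dist = inst.country_distance_km(ko, kd)
                    b.add_cost(("flow", f, ko, kd),
                               _EPS_FLOW * dist * ec.ef_transport_kg_co2e_per_tkm)
            if avail_row:
                b.le(avail_row, 0.0, "mass_balance")
        for kd in countries:
            b.var(("dlv", f, kd))
            row = {("dlv", f, kd): 1.0}
            for ko in (countries if scen.trade_allowed_between_countries else [kd]):
                if b.has(("flow", f, ko, kd)):
                    row[("flow", f, ko, kd)] = -1.0
            b.le(row, 0.0, "mass_balance")
    b.mark("in_country")  # waste & grass feeds carry no cross-border variables

    # -- diets: nutrition, food groups, protein matching ---------------------
    efsa = scen.diet_mode == "efsa_plus_eat_lancet"
    for k in countries:
        pop = inst.population_by_country[k]
        g_per_t = 1e6 / _DAYS / pop  # t/yr -> g/capita/day
        if efsa:
            for nid in NUTRIENTS:
                spec = inst.nutrient_specs[nid]
                coefs = {
                    ("dlv", f, k): g_per_t * (1.0 - chain[f]["cons"])
                    * comp[f].get(nid, 0.0)
                    for f in foods
                }
                if spec.min_per_capita_day is not None and spec.min_per_capita_day > 0:
                    percap_ge(coefs, spec.min_per_capita_day, "nutrition")
                if spec.max_per_capita_day is not None:
                    percap_le(coefs, spec.max_per_capita_day, "nutrition")
            for gid in sorted(inst.food_group_bounds):
                bound = inst.food_group_bounds[gid]
                members = [f for f in foods if group_of[f] == gid]
                if bound.max_energy_share is not None:
                    share = bound.max_energy_share
                    row = {}
                    for f in foods:
                        e = comp[f].get("energy", 0.0) * (1.0 - chain[f]["cons"])
                        w = (1.0 - share) if group_of[f] == gid else -share
                        if e:
                            row[("dlv", f, k)] = w * e
                    if row:
                        b.le(row, 0.0, "food_group")
                    continue
                coefs = {("dlv", f, k): g_per_t * (1.0 - chain[f]["cons"])
                         for f in members}
                if bound.min_g_day > 0 and coefs:
                    percap_ge(coefs, bound.min_g_day, "food_group")
                if bound.max_g_day is not None and coefs:
                    percap_le(coefs, bound.max_g_day, "food_group")
        if scen.diet_mode == "current_protein_by_food_group" and not baseline:
            for gid, cur in sorted(inst.current_supply_protein.get(k, {}).items()):
                if cur <= 0:
                    continue
                members = [f for f in foods if group_of[f] == gid]
                coefs = {("dlv", f, k): g_per_t * comp[f].get("protein", 0.0)
                         for f in members}
                percap_ge(coefs, cur, "protein_match")
        if baseline:
            for gid, cur in sorted(inst.current_supply_protein.get(k, {}).items()):
                if cur <= 0:
                    continue
                members = [f for f in foods if group_of[f] == gid]
                row = {("dlv", f, k): g_per_t * comp[f].get("protein", 0.0)
                       for f in members}
                b.var(("devp", k, gid), cost=1.0 / cur)
                b.var(("devn", k, gid), cost=1.0 / cur)
                row[("devp", k, gid)] = -1.0
                row[("devn", k, gid)] = 1.0
                b.eq(row, cur, "calibration")

    # -- feed pools and animal requirements ----------------------------------
    waste_conc = {"n": rp.waste_n_conc_kg_t, "p": rp.waste_p_conc_kg_t}
    feed_of_crop: dict[str, list[str]] = {}
    for cid, crop in inst.crops.items():
        if crop.feed_value_id:
            feed_of_crop.setdefault(crop.feed_value_id, []).append(cid)

    for k in countries:
        pop = inst.population_by_country[k]
        # consumption-waste pool (t/yr)
        cw_row = {("dlv", f, k): chain[f]["cons"] for f in foods}
        use_row: dict[tuple, float] = {}
        if scen.waste_to_feed_allowed:
            b.var(("fwfeed", k))
            use_row[("fwfeed", k)] = 1.0
            # feed share cap: fwfeed <= waste_to_feed_frac * CW
            row = {("fwfeed", k): 1.0}
            for key, v in cw_row.items():
                row[key] = row.get(key, 0.0) - rp.waste_to_feed_frac * v
            b.le(row, 0.0, "waste")
        if scen.waste_to_compost_allowed:
            b.var(("fwcomp", k))
            use_row[("fwcomp", k)] = 1.0
        if use_row:
            row = dict(use_row)
            for key, v in cw_row.items():
                row[key] = row.get(key, 0.0) - v
            b.le(row, 0.0, "waste")

        for fid in sorted(inst.feed_items):
            item = inst.feed_items[fid]
            supply_row: dict[tuple, float] = {}
            if item.origin == "fodder_crop":
                for cid in feed_of_crop.get(fid, []):
                    if b.has(("cfeed", cid, k)):
                        supply_row[("cfeed", cid, k)] = -1.0
            elif item.origin == "grass":
                gts = [gt for gt, gfid in inst.grass_feed_map.items() if gfid == fid]
                for gt in gts:
                    for z in inst.zones_in(k):
                        if b.has(("grass", z, gt)):
                            gy = inst.grass_yield.get(z, {}).get(gt, 0.0)
                            supply_row[("grass", z, gt)] = -gy
            elif item.origin == "crop_byproduct":
                if not scen.byproducts_to_feed_allowed and \
                        not scen.byproducts_to_fertilizer_allowed:
                    continue
                for cid in sorted(inst.crops):
                    frac = float(_tcf_entry(inst, cid)
                                 .get("byproducts", {}).get(fid, 0.0))
                    if frac > 0 and b.has(("proc", cid, k)):
                        ch = chain.get(cid, {"ph": 0.0})
                        supply_row[("proc", cid, k)] = (
                            supply_row.get(("proc", cid, k), 0.0) - frac)
                if scen.byproducts_to_fertilizer_allowed and supply_row:
                    b.var(("bpfert", fid, k))
                    supply_row[("bpfert", fid, k)] = 1.0
            elif item.origin == "animal_byproduct":
                for sid in sorted(inst.animal_systems):
                    s = inst.animal_systems[sid]
                    if s.byproduct_frac > 0 and b.has(("an", sid, k)):
                        supply_row[("an", sid, k)] = (
                            -s.byproduct_frac * s.output_t_per_unit)
            elif item.origin == "fish_byproduct":
                for st in sorted(inst.fish_stocks):
                    stk = inst.fish_stocks[st]
                    if b.has(("landing", st, k)):
                        supply_row[("landing", st, k)] = -(1.0 - stk.edible_frac)
            elif item.origin == "food_waste":
                if scen.waste_to_feed_allowed:
                    supply_row[("fwfeed", k)] = -1.0
                else:
                    continue
            if not supply_row:
                continue
            feed_ok = (scen.byproducts_to_feed_allowed
                       or item.origin != "crop_byproduct")
            for sid in sorted(inst.animal_systems):
                s = inst.animal_systems[sid]
                if not item.legal_for(s.species) or not feed_ok:
                    continue
                b.var(("q", fid, sid, k))
                supply_row[("q", fid, sid, k)] = (
                    supply_row.get(("q", fid, sid, k), 0.0) + 1.0)
            b.le(supply_row, 0.0, "feed")

        for sid in sorted(inst.animal_systems):
            s = inst.animal_systems[sid]
            if not b.has(("an", sid, k)):
                continue
            aux = s.parent_stock_ratio + s.repro_stock_ratio
            for nut in TRACKED_FEED_NUTRIENTS:
                per_unit = (s.output_t_per_unit
                            * s.requirement_per_t_product.get(nut, 0.0)
                            + aux * s.aux_requirement_per_unit.get(nut, 0.0))
                if per_unit <= 0:
                    continue
                row = {("an", sid, k): -per_unit}
                for fid in sorted(inst.feed_items):
                    if b.has(("q", fid, sid, k)):
                        conc = inst.feed_items[fid].comp_for(s.species).get(nut, 0.0)
                        if conc:
                            row[("q", fid, sid, k)] = conc
                b.ge(row, 0.0, "feed")
            cap_unit = s.intake_capacity_t_dm + aux * s.aux_intake_capacity_t_dm
            row = {("an", sid, k): -cap_unit}
            for fid in sorted(inst.feed_items):
                if b.has(("q", fid, sid, k)):
                    dm = inst.feed_items[fid].comp_for(s.species).get("dm_frac", 0.0)
                    if dm:
                        row[("q", fid, sid, k)] = dm
            b.le(row, 0.0, "feed")

    # -- fertilizer balance ---------------------------------------------------
    grazed_feed_ids = {inst.grass_feed_map[gt] for gt in GRAZED_GRASS_TYPES
                       if gt in inst.grass_feed_map}
    for (cid, zid) in pairs:
        crop = inst.crops[cid]
        zone = inst.zones[zid]
        y = crop.yield_by_zone[zid]
        rrr = crop.residue_to_product_ratio
        n_removal = y * (crop.n_conc_product + rrr * crop.n_conc_residue)
        p_removal = y * (crop.p_conc_product + rrr * crop.p_conc_residue)
        if n_removal <= 0 and p_removal <= 0:
            continue
        n_row: dict[tuple, float] = {("area", cid, zid): -n_removal}
        p_row: dict[tuple, float] = {
            ("area", cid, zid): -p_removal * (1.0 + ec.p_unavoidable_loss)}
        for src in ORGANIC_SOURCES:
            if src == "byproduct" and not scen.byproducts_to_fertilizer_allowed:
                continue
            if src == "compost" and not scen.waste_to_compost_allowed:
                continue
            b.var(("fert", src, cid, zid))
            n_row[("fert", src, cid, zid)] = delivered_n_fraction(src, zone, ec)
            p_row[("fert", src, cid, zid)] = 1.0 / rp.organic_np_ratio[src]
        if scen.artificial_fertilizer_allowed:
            eps = 0.0 if baseline else _EPS_ART
            b.var(("fertN", cid, zid), cost=eps)
            b.var(("fertP", cid, zid), cost=eps)
            n_row[("fertN", cid, zid)] = delivered_n_fraction("artificial", zone, ec)
            p_row[("fertP", cid, zid)] = 1.0
        b.ge(n_row, 0.0, "fertilizer")
        b.ge(p_row, 0.0, "fertilizer")

    # organic-source availability per country
    for k in countries:
        zone_ids = set(inst.zones_in(k))
        per_src_rows: dict[str, dict[tuple, float]] = {
            src: {} for src in ORGANIC_SOURCES}
        for (cid, zid) in pairs:
            if zid not in zone_ids:
                continue
            for src in ORGANIC_SOURCES:
                if b.has(("fert", src, cid, zid)):
                    per_src_rows[src][("fert", src, cid, zid)] = 1.0
        # manure N from MMS (terrestrial systems; grazing N is deposited)
        manure_row = per_src_rows["manure"]
        if manure_row:
            for sid in sorted(inst.animal_systems):
                s = inst.animal_systems[sid]
                if s.is_fish:
                    continue
                for fid in sorted(inst.feed_items):
                    if not b.has(("q", fid, sid, k)) or fid in grazed_feed_ids:
                        continue
                    n_conc = inst.feed_items[fid].comp_for(s.species).get(
                        "n_kg_per_t", 0.0)
                    if n_conc:
                        manure_row[("q", fid, sid, k)] = (
                            manure_row.get(("q", fid, sid, k), 0.0)
                            - (1.0 - s.n_retention_frac) * n_conc)
            b.le(manure_row, 0.0, "fertilizer")
        compost_row = per_src_rows["compost"]
        if compost_row and scen.waste_to_compost_allowed:
            if b.has(("fwcomp", k)):
                compost_row[("fwcomp", k)] = (
                    -(1.0 - rp.compost_n_loss_frac) * waste_conc["n"])
            b.le(compost_row, 0.0, "fertilizer")
        elif compost_row:
            b.le(compost_row, 0.0, "fertilizer")
        excreta_row = per_src_rows["excreta"]
        if excreta_row:
            sludge_n_kg = (inst.current_sludge_t.get(k, 0.0)
                           * rp.sludge_use_frac * rp.sludge_n_frac * 1000.0)
            if mult is not None:
                excreta_row[("mult",)] = -sludge_n_kg
                b.le(excreta_row, 0.0, "fertilizer")
            else:
                b.le(excreta_row, sludge_n_kg, "fertilizer")
        bp_row = per_src_rows["byproduct"]
        if bp_row:
            for fid in sorted(inst.feed_items):
                if b.has(("bpfert", fid, k)):
                    n_conc = inst.feed_items[fid].comp_livestock.get(
                        "n_kg_per_t", 0.0)
                    bp_row[("bpfert", fid, k)] = -n_conc
            b.le(bp_row, 0.0, "fertilizer")

    # artificial fertilizer cap (baseline convention: current total N+P)
    cap_t = scen.artificial_fertilizer_cap_t
    if cap_t is None and baseline:
        cap_t = inst.current_artificial_fertilizer_t
    if cap_t is not None and scen.artificial_fertilizer_allowed:
        row = {}
        for (cid, zid) in pairs:
            if b.has(("fertN", cid, zid)):
                row[("fertN", cid, zid)] = 1.0
                row[("fertP", cid, zid)] = 1.0
        if row:
            b.le(row, cap_t * 1000.0, "fertilizer")

    # -- transport cap ---------------------------------------------------------
    if scen.trade_allowed_between_countries and len(countries) > 1:
        for kd in countries:
            pop = inst.population_by_country[kd]
            row: dict[tuple, float] = {}
            for f in foods:
                for ko in countries:
                    if ko == kd or not b.has(("flow", f, ko, kd)):
                        continue
                    dist = inst.country_distance_km(ko, kd)
                    row[("flow", f, ko, kd)] = (
                        dist * ec.ef_transport_kg_co2e_per_tkm / pop)
            if not row:
                continue
            rhs = scen.transport_co2e_cap_per_capita
            if mult is not None:
                row[("mult",)] = -rhs
                b.le(row, 0.0, "transport")
            else:
                b.le(row, rhs, "transport")
    b.mark("transport")

    # -- objective -------------------------------------------------------------
    if maxpop:
        # stage one maximizes the multiplier alone; land is minimized in a
        # second lexicographic stage (see solve)
        b.cost[b.index[("mult",)]] = -1.0

    bounds = [(lo, up) for lo, up in zip(b.lb, b.ub)]
    spec = ProblemSpec(
        instance=inst,
        scenario=scen,
        var_keys=list(b.keys),
        bounds=bounds,
        cost=np.array(b.cost, dtype=float),
        a_ub=b.matrix(b.rows_ub),
        b_ub=np.array(b.rhs_ub, dtype=float),
        fam_ub=list(b.fam_ub),
        a_eq=b.matrix(b.rows_eq),
        b_eq=np.array(b.rhs_eq, dtype=float),
        fam_eq=list(b.fam_eq),
        families_present=tuple(sorted(b.families)),
        context={"foods": foods, "chain": chain, "group_of": group_of,
                 "index": dict(b.index)},
    )
    return spec


# ---------------------------------------------------------------------------
# solve & extract
# ---------------------------------------------------------------------------

def _run_linprog(spec: ProblemSpec, drop_families: set[str] | None = None,
                 cost: np.ndarray | None = None,
                 bounds: list[tuple[float, float | None]] | None = None):
    drop = drop_families or set()
    if drop:
        keep_ub = [i for i, f in enumerate(spec.fam_ub) if f not in drop]
        keep_eq = [i for i, f in enumerate(spec.fam_eq) if f not in drop]
        a_ub, b_ub = spec.a_ub[keep_ub], spec.b_ub[keep_ub]
        a_eq, b_eq = spec.a_eq[keep_eq], spec.b_eq[keep_eq]
    else:
        a_ub, b_ub, a_eq, b_eq = spec.a_ub, spec.b_ub, spec.a_eq, spec.b_eq
    return linprog(
        spec.cost if cost is None else cost,
        A_ub=a_ub if a_ub.shape[0] else None,
        b_ub=b_ub if len(b_ub) else None,
        A_eq=a_eq if a_eq.shape[0] else None,
        b_eq=b_eq if len(b_eq) else None,
        bounds=spec.bounds if bounds is None else bounds,
        method="highs",
    )


def _diagnose_infeasibility(spec: ProblemSpec) -> list[str]:
    """Families whose removal restores feasibility (binding families)."""
    implicated = []
    for fam in sorted(set(spec.fam_ub) | set(spec.fam_eq)):
        res = _run_linprog(spec, drop_families={fam})
        if res.status == 0:
            implicated.append(fam)
    return implicated


def solve(spec: ProblemSpec, tolerance: float = 1e-7,
          seed: int | None = None, attach_ghg: bool = True) -> Solution:
    """Solve an assembled problem and extract a structured Solution.

    Deterministic for a fixed problem: variable order is fixed at build time
    and HiGHS is deterministic; ``seed`` is accepted for interface symmetry
    with stochastic components but does not influence the solve.
    """
    if spec.scenario.objective == "max_population_fed":
        # stage one: maximize the multiplier with a pure objective (tiny
        # tie-break costs below the solver's dual tolerance are dropped)
        idx_mult = spec.context["index"][("mult",)]
        cost1 = np.zeros_like(spec.cost)
        cost1[idx_mult] = -1.0
        res = _run_linprog(spec, cost=cost1)
    else:
        res = _run_linprog(spec)
    if res.status == 0 and spec.scenario.objective == "max_population_fed":
        # lexicographic second stage: hold the maximal population and pick
        # the least-land way to feed it
        m_star = float(res.x[idx_mult]) * (1.0 - 1e-9)
        bounds2 = list(spec.bounds)
        bounds2[idx_mult] = (m_star, m_star)
        cost2 = np.array(spec.cost)
        cost2[idx_mult] = 0.0
        for key, i in spec.context["index"].items():
            if key[0] in ("area", "grass"):
                cost2[i] = 1.0
        res2 = _run_linprog(spec, cost=cost2, bounds=bounds2)
        if res2.status == 0:
            res = res2
    if res.status == 2:
        families = _diagnose_infeasibility(spec)
        raise InfeasibleProblemError(
            "problem infeasible; binding constraint families: "
            + (", ".join(families) if families else "(not isolated)"),
            families)
    if res.status == 3:
        raise RuntimeError("problem unbounded; objective "
                           f"{spec.scenario.objective!r} has an unbounded ray")
    if res.status != 0:
        raise RuntimeError(f"solver failed with status {res.status}: {res.message}")

    x = np.asarray(res.x)
    x[np.abs(x) < 1e-11] = 0.0
    idx = spec.context["index"]

    def val(key: tuple) -> float:
        i = idx.get(key)
        return float(x[i]) if i is not None else 0.0

    inst = spec.instance
    scen = spec.scenario
    foods = spec.context["foods"]
    chain = spec.context["chain"]
    mult = val(("mult",)) if ("mult",) in idx else 1.0

    sol = Solution(status="optimal", population_multiplier=mult)
    sol.population_fed = inst.total_population() * mult
    for key in spec.var_keys:
        v = val(key)
        if v <= 0.0:
            continue
        kind = key[0]
        if kind == "area":
            sol.area[(key[1], key[2])] = v
        elif kind == "grass":
            sol.grass_area[(key[1], key[2])] = v
        elif kind == "an":
            sol.animals[(key[1], key[2])] = v
        elif kind == "q":
            sol.feed_alloc[(key[1], key[2], key[3])] = v
        elif kind == "flow":
            sol.flows[(key[1], key[2], key[3])] = v
        elif kind == "dlv":
            sol.delivered[(key[1], key[2])] = v
        elif kind == "proc":
            sol.crop_use[(key[1], key[2], "processed")] = v
        elif kind == "cfeed":
            sol.crop_use[(key[1], key[2], "feed")] = v
        elif kind == "bpfert":
            sol.byproduct_to_fert[(key[1], key[2])] = v
        elif kind == "fwfeed":
            sol.waste_to_feed_t[key[1]] = v
        elif kind == "fwcomp":
            sol.waste_to_compost_t[key[1]] = v
        elif kind == "landing":
            sol.landings[(key[1], key[2])] = v
        elif kind == "fert":
            src, cid, zid = key[1], key[2], key[3]
            n = v
            p = v / inst.residual_params.organic_np_ratio[src]
            sol.fertilizer[(src, cid, zid)] = (n, p)
    for (cid, zid) in {(k[1], k[2]) for k in spec.var_keys if k[0] == "fertN"}:
        n = val(("fertN", cid, zid))
        p = val(("fertP", cid, zid))
        if n > 0 or p > 0:
            sol.fertilizer[("artificial", cid, zid)] = (n, p)

    for f in foods:
        for k in inst.countries:
            t = sol.delivered.get((f, k), 0.0)
            if t <= 0:
                continue
            pop = inst.population_by_country[k] * mult
            sol.diet[(f, k)] = (t * (1.0 - chain[f]["cons"]) * 1e6
                                / _DAYS / pop)

    if scen.objective == "min_agricultural_land":
        sol.objective_value = sol.total_land_ha()
    elif scen.objective == "max_population_fed":
        sol.objective_value = sol.population_fed
    else:
        sol.objective_value = float(res.fun)
    sol.meta = {
        "solver_objective": float(res.fun),
        "n_vars": spec.n_vars,
        "n_constraints": spec.n_constraints,
        "families": list(spec.families_present),
        "scenario": scen.name,
        "iterations": int(getattr(res, "nit", 0) or 0),
    }
    if attach_ghg:
        sol.ghg = build_inventory(inst, scen, sol)
    return sol


# ---------------------------------------------------------------------------
# GHG inventory from a solution
# ---------------------------------------------------------------------------

def build_inventory(inst: FoodSystemInstance, scen: ScenarioConfig,
                    sol: Solution) -> ghg_mod.GHGInventory:
    """Compute the post-hoc emission inventory of a solved scenario."""
    ec = inst.emission_constants
    inv = ghg_mod.GHGInventory(gwp_ch4=ec.gwp_ch4_biogenic, gwp_n2o=ec.gwp_n2o)
    grazed_feed_ids = {inst.grass_feed_map[gt] for gt in GRAZED_GRASS_TYPES
                      if gt in inst.grass_feed_map}

    for sid in sorted(inst.animal_systems):
        s = inst.animal_systems[sid]
        for k in inst.countries:
            ration = {fid: t for (fid, s2, kk), t in sol.feed_alloc.items()
                      if s2 == sid and kk == k}
            if not ration:
                continue
            n_intake = sum(
                t * inst.feed_items[fid].comp_for(s.species).get("n_kg_per_t", 0.0)
                for fid, t in ration.items())
            n_grazed = sum(
                t * inst.feed_items[fid].comp_for(s.species).get("n_kg_per_t", 0.0)
                for fid, t in ration.items() if fid in grazed_feed_ids)
            if s.is_fish:
                inv.add("aquaculture_N2O", "N2O",
                        ghg_mod.aquaculture_n2o(
                            n_intake * (1.0 - s.n_retention_frac), ec))
                continue
            ge = sum(
                t * inst.feed_items[fid].comp_for(s.species).get(
                    "gross_energy_mj_per_t", 0.0)
                for fid, t in ration.items())
            if s.is_ruminant and s.ym_percent:
                inv.add("enteric", "CH4", ghg_mod.enteric_ch4(ge, s.ym_percent, ec))
            graze_share = (n_grazed / n_intake) if n_intake > 0 else 0.0
            n_ex = n_intake * (1.0 - s.n_retention_frac)
            n_mms = n_ex * (1.0 - graze_share)
            n_pasture = n_ex * graze_share
            vs = ration_volatile_solids(ration, s.species, inst.feed_items)
            mcf = s.mms_params.get("MCF", 0.0)
            b0 = s.mms_params.get("B0", 0.0)
            inv.add("manure_mgmt_CH4", "CH4",
                    ghg_mod.manure_ch4(vs * (1.0 - graze_share), mcf, b0, ec)
                    + ghg_mod.manure_ch4(vs * graze_share, ec.mcf_pasture, b0, ec))
            inv.add("manure_N2O", "N2O", ghg_mod.manure_n2o(
                n_mms,
                s.mms_params.get("n2o_ef_direct", 0.0),
                s.mms_params.get("volatilization_frac", 0.0),
                ec.soil_ef("manure", "wet")["ef_volat"]))
            if n_pasture > 0:
                inv.add("grassland_N2O", "N2O",
                        ghg_mod.grassland_n2o(n_pasture, ec))

    # soil N2O from fertilization + organic-soil term
    by_zone_src: dict[tuple[str, str], float] = {}
    for (src, cid, zid), (n_kg, _p) in sol.fertilizer.items():
        by_zone_src[(zid, src)] = by_zone_src.get((zid, src), 0.0) + n_kg
    soil = 0.0
    for (zid, src), n_kg in sorted(by_zone_src.items()):
        zone = inst.zones[zid]
        moist = "wet" if zone.is_wet else "dry"
        soil += ghg_mod.soil_n2o({src: n_kg}, moist, ec)
    peat_area = sum(
        a for (cid, zid), a in sol.area.items()
        if inst.zones[zid].is_organic_soil)
    inv.add("soil_N2O", "N2O", soil)
    if peat_area > 0:
        inv.add("organic_soil_N2O", "N2O",
                peat_area * ec.ef_organic_soil_kg_n2o_per_ha)

    compost_n_kg = sum(sol.waste_to_compost_t.values()) \
        * inst.residual_params.waste_n_conc_kg_t
    if compost_n_kg > 0:
        n2o, ch4 = ghg_mod.compost_emissions(compost_n_kg, ec)
        inv.add("compost", "N2O", n2o)
        inv.add("compost", "CH4", ch4)

    art_n = sum(n for (src, _c, _z), (n, _p) in sol.fertilizer.items()
                if src == "artificial")
    art_p = sum(p for (src, _c, _z), (_n, p) in sol.fertilizer.items()
                if src == "artificial")
    if art_n > 0 or art_p > 0:
        inv.add("fertilizer_production", "CO2",
                ghg_mod.fertilizer_production_emissions(
                    art_n / 1000.0, art_p / 1000.0, ec))

    tkm_by_dest: dict[str, float] = {}
    for (f, ko, kd), t in sol.flows.items():
        if ko == kd:
            continue
        tkm_by_dest[kd] = tkm_by_dest.get(kd, 0.0) \
            + t * inst.country_distance_km(ko, kd)
    transport_kg, _flagged = ghg_mod.transport_emissions(tkm_by_dest, ec)
    if transport_kg > 0:
        inv.add("transport", "CO2", transport_kg)
    return inv


# ---------------------------------------------------------------------------
# solution verification (used on every solver output in the test suite)
# ---------------------------------------------------------------------------

def verify_solution(inst: FoodSystemInstance, scen: ScenarioConfig,
                    sol: Solution, tol: float = 1e-6) -> list[str]:
    """Check a solution against every constraint family; return violations."""
    from .nutrition import (diet_nutrients, food_group_violations,
                            nutrient_bound_violations, protein_supply_match)

    out: list[str] = []
    rp = inst.residual_params
    ec = inst.emission_constants
    mult = sol.population_multiplier
    foods = inst.food_ids()
    chain = {f: _chain(inst, f) for f in foods}

    def rel_ok(value: float, limit: float) -> bool:
        return value <= limit + tol * max(1.0, abs(limit))

    # land / rotation / suitability
    for zid, zone in inst.zones.items():
        used = sum(a for (c, z), a in sol.area.items() if z == zid)
        if not rel_ok(used, zone.cropland_ha()):
            out.append(f"land: zone {zid} cropland exceeded")
        caps = suitable_crops(zone, inst)
        for (cid, z), a in sol.area.items():
            if z != zid:
                continue
            if cid not in caps:
                out.append(f"suitability: {cid} grown in unsuitable zone {zid}")
            elif not scen.fixed_current_areas and not rel_ok(a, caps[cid]):
                out.append(f"rotation: {cid} in {zid} exceeds cap")
        for gt in GRASS_TYPES:
            ga = sol.grass_area.get((zid, gt), 0.0)
            if not rel_ok(ga, zone.area_by_land_type.get(gt, 0.0)):
                out.append(f"land: grass area {gt} in {zid} exceeded")

    # feed legality & ruminant waste ban
    for (fid, sid, k), t in sol.feed_alloc.items():
        if t <= tol:
            continue
        s = inst.animal_systems[sid]
        item = inst.feed_items[fid]
        if not item.legal_for(s.species):
            out.append(f"feed: {fid} fed to {sid} ({s.species}) illegally")
        if item.origin == "food_waste" and s.species in RUMINANT_SPECIES:
            out.append(f"feed: food waste fed to ruminant system {sid}")

    # waste availability & 35% share
    for k in inst.countries:
        cw = sum(sol.delivered.get((f, k), 0.0) * chain[f]["cons"] for f in foods)
        fed = sol.waste_to_feed_t.get(k, 0.0)
        comp = sol.waste_to_compost_t.get(k, 0.0)
        if not rel_ok(fed, rp.waste_to_feed_frac * cw):
            out.append(f"waste: feed share above {rp.waste_to_feed_frac:.0%} in {k}")
        if not rel_ok(fed + comp, cw):
            out.append(f"waste: waste use exceeds the pool in {k}")

    # nutrition, food groups, protein match
    for k in inst.countries:
        diet = {f: sol.diet.get((f, k), 0.0) for f in foods}
        comp_tbl = {f: inst.food_composition_of(f) for f in foods}
        if scen.diet_mode == "efsa_plus_eat_lancet":
            vec = diet_nutrients(diet, comp_tbl)
            for v in nutrient_bound_violations(vec, inst.nutrient_specs):
                if abs(v.value - v.limit) > tol * max(1.0, abs(v.limit)) * 100:
                    out.append(f"nutrition: {k} {v}")
            energy = {f: comp_tbl[f].get("energy", 0.0) for f in foods}
            group_of = {f: inst.food_group_of(f) for f in foods}
            for gv in food_group_violations(diet, group_of,
                                            inst.food_group_bounds, energy):
                if abs(gv.value - gv.limit) > tol * max(1.0, abs(gv.limit)) * 100:
                    out.append(f"food_group: {k} {gv.group} {gv.bound}")
        if scen.diet_mode == "current_protein_by_food_group" \
                and scen.objective != "calibrate_baseline":
            pop = inst.population_by_country[k] * mult
            delivered: dict[str, dict[str, float]] = {k: {}}
            for f in foods:
                g = inst.food_group_of(f)
                t = sol.delivered.get((f, k), 0.0)
                prot = inst.food_composition_of(f).get("protein", 0.0)
                delivered[k][g] = delivered[k].get(g, 0.0) \
                    + t * prot * 1e6 / _DAYS / pop
            cur = {k: {g: v * 1.0 for g, v in
                       inst.current_supply_protein.get(k, {}).items()}}
            for sf in protein_supply_match(delivered, cur):
                if sf.shortfall_g_day > tol * max(1.0, sf.required_g_day) * 100:
                    out.append(f"protein_match: {k} {sf.group} short "
                               f"{sf.shortfall_g_day:.4g} g/day")

    # fertilizer balance (delivered-N crediting, source-specific losses)
    for (cid, zid), a in sol.area.items():
        crop = inst.crops[cid]
        zone = inst.zones[zid]
        y = crop.yield_by_zone.get(zid, 0.0)
        rrr = crop.residue_to_product_ratio
        n_removal = a * y * (crop.n_conc_product + rrr * crop.n_conc_residue)
        p_req = a * y * (crop.p_conc_product + rrr * crop.p_conc_residue) \
            * (1.0 + ec.p_unavoidable_loss)
        n_del = p_del = 0.0
        for (src, c2, z2), (n_kg, p_kg) in sol.fertilizer.items():
            if c2 != cid or z2 != zid:
                continue
            if src == "artificial":
                n_del += n_kg * delivered_n_fraction(src, zone, ec)
                p_del += p_kg
            else:
                n_del += n_kg * delivered_n_fraction(src, zone, ec)
                p_del += n_kg / rp.organic_np_ratio[src]
        if n_removal > 0 and n_del + tol * max(1.0, n_removal) * 10 < n_removal:
            out.append(f"fertilizer: N deficit for {cid} in {zid}")
        if p_req > 0 and p_del + tol * max(1.0, p_req) * 10 < p_req:
            out.append(f"fertilizer: P deficit for {cid} in {zid}")

    # fishery caps
    for (st, k), t in sol.landings.items():
        cap = inst.fish_stocks[st].msy_cap_t.get(k, 0.0)
        if not rel_ok(t, cap):
            out.append(f"fishery: landings of {st} in {k} exceed MSY")

    # transport cap
    for kd in inst.countries:
        kg = sum(t * inst.country_distance_km(ko, kd)
                 * ec.ef_transport_kg_co2e_per_tkm
                 for (f, ko, k2), t in sol.flows.items()
                 if k2 == kd and ko != kd)
        pop = inst.population_by_country[kd] * mult
        if pop > 0 and not rel_ok(kg / pop, scen.transport_co2e_cap_per_capita):
            out.append(f"transport: per-capita cap exceeded in {kd}")

    # commodity ledger: deliveries never exceed flows, flows never exceed
    # availability (production + processing), per food and country
    for f in foods:
        for ko in inst.countries:
            shipped = sum(t for (f2, o, d), t in sol.flows.items()
                          if f2 == f and o == ko)
            avail = _food_availability(inst, sol, f, ko, chain[f])
            if not rel_ok(shipped, avail):
                out.append(f"mass_balance: {f} shipped from {ko} exceeds supply")
        for kd in inst.countries:
            got = sum(t for (f2, o, d), t in sol.flows.items()
                      if f2 == f and d == kd)
            if not rel_ok(sol.delivered.get((f, kd), 0.0), got):
                out.append(f"mass_balance: {f} delivered in {kd} exceeds inflow")
    return out


def _food_availability(inst: FoodSystemInstance, sol: Solution, f: str,
                       ko: str, ch: dict[str, float]) -> float:
    post = (1.0 - ch["proc"]) * (1.0 - ch["dist"])
    if f in inst.crops:
        main = float(_tcf_entry(inst, f).get("main_fraction", 1.0))
        return sol.crop_use.get((f, ko, "processed"), 0.0) * main * post
    if f == "wild_fish":
        total = 0.0
        for st, stk in inst.fish_stocks.items():
            total += sol.landings.get((st, ko), 0.0) * stk.edible_frac \
                * (1.0 - ch["ph"]) * post
        return total
    for sid, s in inst.animal_systems.items():
        if s.food_id == f:
            units = sol.animals.get((sid, ko), 0.0)
            return units * s.output_t_per_unit * (1.0 - ch["ph"]) * post
    return 0.0
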