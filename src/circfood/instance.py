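"""Domain types for food-system instances and solutions.

A :class:`FoodSystemInstance` is the complete parameterization of one model
run: zones with land areas, crops with zone-specific yields, animal and fish
systems, feed items, residual-stream parameters, emission factors, nutrient
and food-group bounds, population and a "current" baseline for calibration.

Units are fixed artifact-wide and converted at parse time:

* land areas — ha
* biomass — t fresh matter / yr
* nutrient masses (N, P) — kg
* feed energy — MJ
* diets — g fresh / capita / day
* emissions — kg gas / yr, aggregated to kg CO2e / yr

Instances serialize to a human-editable YAML dialect; solutions export to a
directory of delimited tables with units in the headers.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .nutrients import (
    ANIMAL_GROUPS,
    FODDER_GROUP,
    FOOD_GROUPS,
    NUTRIENTS,
    RUMINANT_SPECIES,
    FISH_SPECIES,
    SPECIES_FOOD_GROUP,
    WASTE_STAGES,
)

LAND_TYPES: tuple[str, ...] = (
    "cropland",
    "temporary_grassland",
    "permanent_pasture",
    "rangeland",
)
GRASS_TYPES: tuple[str, ...] = LAND_TYPES[1:]

#: Fertilizer source categories, ordered: the four organic sources plus
#: artificial fertilizer.
FERTILIZER_SOURCES: tuple[str, ...] = (
    "byproduct",
    "manure",
    "compost",
    "excreta",
    "artificial",
)

FEED_ORIGINS: tuple[str, ...] = (
    "fodder_crop",
    "grass",
    "crop_byproduct",
    "animal_byproduct",
    "food_waste",
    "fish_byproduct",
)

#: Feed-composition fields, per t fresh feed unless noted.
FEED_COMP_FIELDS: tuple[str, ...] = (
    "dm_frac",              # t dry matter / t fresh
    "energy_mj_per_t",      # metabolizable energy, requirement currency
    "dig_protein_kg_per_t", # digestible protein
    "gross_energy_mj_per_t",# gross energy (enteric CH4 substrate)
    "dig_om_frac",          # digestibility of organic matter (VS computation)
    "n_kg_per_t",
    "p_kg_per_t",
)

#: Feed nutrients the ration constraints track by default.
TRACKED_FEED_NUTRIENTS: tuple[str, ...] = ("energy_mj_per_t", "dig_protein_kg_per_t")


# ---------------------------------------------------------------------------
# dataclass helpers
# ---------------------------------------------------------------------------

def _check_keys(cls, data: Mapping[str, Any], where: str) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise InstanceParseError(
            f"{where}: unknown key(s) {sorted(unknown)!r} for {cls.__name__}"
        )


class InstanceParseError(ValueError):
    """Raised when an instance file cannot be parsed into the schema."""


class DanglingReferenceError(ValueError):
    """Raised when a cross-reference in an instance does not resolve."""


@dataclass(frozen=True)
class Violation:
    """One validation finding: the type, object id and rule violated."""

    type: str
    obj_id: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.type}[{self.obj_id}]: {self.rule}"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Zone:
    zone_id: str
    country_id: str
    area_by_land_type: dict[str, float]
    climate_class: str            # e.g. "temperate_wet"
    soil_class: str               # "organic" flags drained peat soils
    coordinates: tuple[float, float] = (0.0, 0.0)  # km in a planar frame

    @property
    def is_wet(self) -> bool:
        return self.climate_class.endswith("wet")

    @property
    def is_organic_soil(self) -> bool:
        return self.soil_class == "organic"

    def cropland_ha(self) -> float:
        return self.area_by_land_type.get("cropland", 0.0)


@dataclass
class Crop:
    crop_id: str
    food_group: str               # one of FOOD_GROUPS or "fodder"
    yield_by_zone: dict[str, float]     # t fresh / ha; absent => unsuitable
    rotation_max_frequency: float       # fraction of years, e.g. 1/6
    residue_to_product_ratio: float = 0.0
    n_conc_product: float = 0.0         # kg N / t fresh
    p_conc_product: float = 0.0         # kg P / t fresh
    n_conc_residue: float = 0.0
    p_conc_residue: float = 0.0
    food_composition: dict[str, float] | None = None  # per g fresh
    feed_value_id: str | None = None    # FeedItem used when fed whole
    acreage_cap_by_zone: dict[str, float] | None = None

    @property
    def is_food_crop(self) -> bool:
        return self.food_group != FODDER_GROUP


@dataclass
class AnimalSystem:
    system_id: str
    species: str                  # dairy/beef/pig/broiler/layer/salmon/tilapia
    productivity_level: str       # high/medium/low (fish: "single")
    output_t_per_unit: float      # t product / producing unit / yr
    requirement_per_t_product: dict[str, float]   # feed nutrient -> amount / t
    intake_capacity_t_dm: float   # t DM / producing animal-year
    parent_stock_ratio: float = 0.0
    repro_stock_ratio: float = 0.0
    aux_requirement_per_unit: dict[str, float] = field(default_factory=dict)
    aux_intake_capacity_t_dm: float = 0.0
    product_composition: dict[str, float] = field(default_factory=dict)
    n_retention_frac: float = 0.0  # fraction of N intake retained in product
    p_retention_frac: float = 0.0
    byproduct_frac: float = 0.0    # t feed by-product / t product
    mms_params: dict[str, float] = field(default_factory=dict)
    ym_percent: float | None = None  # ruminants only
    grazing_allowed: bool = False

    @property
    def is_ruminant(self) -> bool:
        return self.species in RUMINANT_SPECIES

    @property
    def is_fish(self) -> bool:
        return self.species in FISH_SPECIES

    @property
    def food_id(self) -> str:
        return f"{self.system_id}_product"

    @property
    def food_group(self) -> str:
        return SPECIES_FOOD_GROUP[self.species]


@dataclass
class FeedItem:
    feed_id: str
    origin: str
    comp_livestock: dict[str, float] = field(default_factory=dict)
    comp_fish: dict[str, float] | None = None
    legality: dict[str, bool] = field(default_factory=dict)  # species -> ok
    wet: bool = False

    def legal_for(self, species: str) -> bool:
        return self.legality.get(species, True)

    def comp_for(self, species: str) -> dict[str, float]:
        if species in FISH_SPECIES and self.comp_fish is not None:
            return self.comp_fish
        return self.comp_livestock


@dataclass
class NutrientSpec:
    nutrient_id: str
    unit: str
    min_per_capita_day: float | None = None
    max_per_capita_day: float | None = None


@dataclass
class FoodGroupBound:
    group_id: str
    min_g_day: float = 0.0
    max_g_day: float | None = None
    max_energy_share: float | None = None  # grains: share of energy intake


@dataclass
class ResidualParams:
    waste_to_feed_frac: float = 0.35
    sludge_use_frac: float = 0.36
    sludge_n_frac: float = 0.075
    sludge_p_frac: float = 0.012
    compost_cn_ratio: float = 15.0
    compost_n_loss_frac: float = 0.05   # gaseous N loss during composting
    waste_n_conc_kg_t: float = 5.0      # N in mixed consumption waste
    waste_p_conc_kg_t: float = 0.8
    # (food, stage) -> fraction lost at that stage
    stage_waste_fracs: dict[str, dict[str, float]] = field(default_factory=dict)
    # crop -> {"main_fraction": f, "byproducts": {feed_id: f}}
    tcf: dict[str, dict[str, Any]] = field(default_factory=dict)
    # organic fertilizer source class -> fixed N:P mass ratio
    organic_np_ratio: dict[str, float] = field(
        default_factory=lambda: {
            "byproduct": 6.0,
            "manure": 4.0,
            "compost": 6.0,
            "excreta": 6.25,
        }
    )

    def stage_fracs_for(self, food_id: str) -> dict[str, float]:
        return self.stage_waste_fracs.get(food_id, {})


def _default_ef_soil() -> dict[str, dict[str, float]]:
    # Tier-1 style emission/loss factors per fertilizer source and climate
    # moisture; direct EFs in kg N2O-N / kg N, the rest are N fractions.
    table: dict[str, dict[str, float]] = {}
    for src in FERTILIZER_SOURCES:
        synthetic = src == "artificial"
        for moist in ("wet", "dry"):
            table[f"{src}|{moist}"] = {
                "ef_direct": 0.01 if synthetic else (0.006 if moist == "wet" else 0.005),
                "frac_volat": 0.10 if synthetic else 0.21,
                "ef_volat": 0.010,
                "frac_leach": 0.24 if moist == "wet" else 0.0,
                "ef_leach": 0.011,
            }
    return table


@dataclass
class EmissionConstants:
    ch4_energy_mj_per_kg: float = 55.65   # gross energy content of methane
    ch4_m3_to_kg: float = 0.67
    gwp_ch4_biogenic: float = 28.0
    gwp_n2o: float = 265.0
    n_to_n2o: float = 44.0 / 28.0
    aquaculture_n2o_frac: float = 0.018
    p_unavoidable_loss: float = 0.125
    ef_soil: dict[str, dict[str, float]] = field(default_factory=_default_ef_soil)
    ef_organic_soil_kg_n2o_per_ha: float = 13.0 * 44.0 / 28.0 / 1000.0 * 1000.0
    ef_fert_prod_n_kg_co2e_per_kg: float = 5.0
    ef_fert_prod_p_kg_co2e_per_kg: float = 2.0
    ef_transport_kg_co2e_per_tkm: float = 0.1
    ef_pasture_n2o_direct: float = 0.006  # kg N2O-N / kg N deposited
    mcf_pasture: float = 0.01
    compost_n2o_ef: float = 0.01          # kg N2O-N / kg N composted
    compost_c_to_ch4: float = 0.025       # fraction of compost C emitted as CH4

    def soil_ef(self, source: str, moisture: str) -> dict[str, float]:
        key = f"{source}|{moisture}"
        if key not in self.ef_soil:
            raise KeyError(f"no soil emission factors for {key!r}")
        return self.ef_soil[key]


@dataclass
class FishStock:
    stock_id: str
    species: str
    msy_cap_t: dict[str, float]   # country -> t fresh landings / yr
    edible_frac: float = 0.6
    food_composition: dict[str, float] = field(default_factory=dict)
    n_conc_product: float = 25.0  # kg N / t fresh edible
    p_conc_product: float = 4.0


@dataclass
class FoodSystemInstance:
    name: str
    zones: dict[str, Zone]
    crops: dict[str, Crop]
    animal_systems: dict[str, AnimalSystem]
    feed_items: dict[str, FeedItem]
    fish_stocks: dict[str, FishStock]
    nutrient_specs: dict[str, NutrientSpec]
    food_group_bounds: dict[str, FoodGroupBound]
    residual_params: ResidualParams
    emission_constants: EmissionConstants
    population_by_country: dict[str, float]
    country_coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)
    # zone -> grass land type -> t fresh / ha harvestable
    grass_yield: dict[str, dict[str, float]] = field(default_factory=dict)
    # grass land type -> feed item carrying its feed value
    grass_feed_map: dict[str, str] = field(default_factory=dict)
    # country -> food group -> g protein / capita / day (current supply)
    current_supply_protein: dict[str, dict[str, float]] = field(default_factory=dict)
    # crop -> zone -> ha currently cultivated
    current_areas: dict[str, dict[str, float]] = field(default_factory=dict)
    current_artificial_fertilizer_t: float = 0.0   # t N+P / yr, cap in baseline
    current_sludge_t: dict[str, float] = field(default_factory=dict)  # t fresh
    climate_classes: tuple[str, ...] = (
        "temperate_wet",
        "temperate_dry",
        "boreal_wet",
        "boreal_dry",
    )
    soil_classes: tuple[str, ...] = ("clay", "sand", "organic", "other")

    # -- derived accessors ---------------------------------------------------

    @property
    def countries(self) -> list[str]:
        return sorted(self.population_by_country)

    def zones_in(self, country: str) -> list[str]:
        return sorted(z for z, zn in self.zones.items() if zn.country_id == country)

    def total_population(self) -> float:
        return float(sum(self.population_by_country.values()))

    def country_distance_km(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        xa, ya = self.country_coordinates[a]
        xb, yb = self.country_coordinates[b]
        return math.hypot(xa - xb, ya - yb)

    def food_ids(self) -> list[str]:
        """All food commodities: food crops, animal products, wild fish."""
        foods = [c for c, cr in self.crops.items() if cr.is_food_crop]
        foods += [s.food_id for s in self.animal_systems.values()]
        if self.fish_stocks:
            foods.append("wild_fish")
        return sorted(foods)

    def food_group_of(self, food_id: str) -> str:
        if food_id in self.crops:
            return self.crops[food_id].food_group
        if food_id == "wild_fish":
            return "fish"
        for s in self.animal_systems.values():
            if s.food_id == food_id:
                return s.food_group
        raise KeyError(f"unknown food {food_id!r}")

    def food_composition_of(self, food_id: str) -> dict[str, float]:
        if food_id in self.crops:
            comp = self.crops[food_id].food_composition
            if comp is None:
                raise KeyError(f"crop {food_id!r} has no food composition")
            return comp
        if food_id == "wild_fish":
            stock = next(iter(sorted(self.fish_stocks)))
            return self.fish_stocks[stock].food_composition
        for s in self.animal_systems.values():
            if s.food_id == food_id:
                return s.product_composition
        raise KeyError(f"no composition for food {food_id!r}")

    def food_np_conc(self, food_id: str) -> tuple[float, float]:
        """(kg N, kg P) per t fresh of a food commodity."""
        if food_id in self.crops:
            c = self.crops[food_id]
            return c.n_conc_product, c.p_conc_product
        if food_id == "wild_fish":
            stock = self.fish_stocks[next(iter(sorted(self.fish_stocks)))]
            return stock.n_conc_product, stock.p_conc_product
        for s in self.animal_systems.values():
            if s.food_id == food_id:
                prot_per_g = s.product_composition.get("protein", 0.0)
                n = prot_per_g * 1000.0 / 6.25  # kg N / t fresh
                return n, n / 7.0
        raise KeyError(food_id)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_instance(inst: FoodSystemInstance) -> list[Violation]:
    """Check every type invariant; return violations as data (never raises)."""
    v: list[Violation] = []

    def bad(type_: str, obj: str, rule: str) -> None:
        v.append(Violation(type_, obj, rule))

    for zid, z in sorted(inst.zones.items()):
        for lt in LAND_TYPES:
            if lt not in z.area_by_land_type:
                bad("Zone", zid, f"missing land type {lt!r}")
            elif z.area_by_land_type[lt] < 0:
                bad("Zone", zid, f"negative area for {lt!r}")
        if z.climate_class not in inst.climate_classes:
            bad("Zone", zid, f"climate_class {z.climate_class!r} not declared")
        if z.soil_class not in inst.soil_classes:
            bad("Zone", zid, f"soil_class {z.soil_class!r} not declared")
        if z.country_id not in inst.population_by_country:
            bad("Zone", zid, f"country {z.country_id!r} has no population entry")

    valid_groups = set(FOOD_GROUPS) | {FODDER_GROUP}
    for cid, c in sorted(inst.crops.items()):
        if not (0.0 < c.rotation_max_frequency <= 1.0):
            bad("Crop", cid, "rotation_max_frequency must be in (0, 1]")
        if not c.yield_by_zone:
            bad("Crop", cid, "yield defined for no zone")
        for zid in c.yield_by_zone:
            if zid not in inst.zones:
                bad("Crop", cid, f"yield references unknown zone {zid!r}")
        for fld in ("n_conc_product", "p_conc_product", "n_conc_residue",
                    "p_conc_residue", "residue_to_product_ratio"):
            if getattr(c, fld) < 0:
                bad("Crop", cid, f"{fld} must be >= 0")
        if c.food_group not in valid_groups:
            bad("Crop", cid, f"unknown food group {c.food_group!r}")
        if c.is_food_crop and c.food_composition is None:
            bad("Crop", cid, "food crop lacks a food composition")
        if c.food_composition is not None:
            missing = set(NUTRIENTS) - set(c.food_composition)
            if missing:
                bad("Crop", cid, f"composition missing nutrients {sorted(missing)[:3]}...")
        if c.feed_value_id is not None and c.feed_value_id not in inst.feed_items:
            bad("Crop", cid, f"feed_value_id {c.feed_value_id!r} unresolved")

    for sid, s in sorted(inst.animal_systems.items()):
        if s.species not in SPECIES_FOOD_GROUP:
            bad("AnimalSystem", sid, f"unknown species {s.species!r}")
        if s.parent_stock_ratio < 0 or s.repro_stock_ratio < 0:
            bad("AnimalSystem", sid, "stock ratios must be >= 0")
        for fld in ("n_retention_frac", "p_retention_frac"):
            if not (0.0 <= getattr(s, fld) <= 1.0):
                bad("AnimalSystem", sid, f"{fld} must be in [0, 1]")
        if s.ym_percent is not None and not s.is_ruminant:
            bad("AnimalSystem", sid, "Ym set for a non-ruminant species")
        if s.is_ruminant and s.ym_percent is None:
            bad("AnimalSystem", sid, "ruminant system lacks Ym")
        if s.grazing_allowed and not s.is_ruminant:
            bad("AnimalSystem", sid, "grazing allowed for non-ruminant")
        if s.output_t_per_unit <= 0:
            bad("AnimalSystem", sid, "output_t_per_unit must be > 0")

    for fid, f in sorted(inst.feed_items.items()):
        if f.origin not in FEED_ORIGINS:
            bad("FeedItem", fid, f"unknown origin {f.origin!r}")
        for comp in (f.comp_livestock, f.comp_fish or {}):
            for k, val in comp.items():
                if val < 0:
                    bad("FeedItem", fid, f"negative composition value {k!r}")
        if f.origin == "food_waste":
            for sp in RUMINANT_SPECIES:
                if f.legal_for(sp):
                    bad("FeedItem", fid,
                        f"food-waste feed legal for ruminant species {sp!r}; "
                        "ruminants may not be fed food losses or waste")

    if set(inst.nutrient_specs) != set(NUTRIENTS):
        bad("NutrientSpec", "*",
            f"instance must declare exactly the 42 tracked nutrients "
            f"({len(inst.nutrient_specs)} declared)")
    for nid, spec in sorted(inst.nutrient_specs.items()):
        lo, hi = spec.min_per_capita_day, spec.max_per_capita_day
        if lo is not None and hi is not None and lo > hi:
            bad("NutrientSpec", nid, "min exceeds max")

    for gid, b in sorted(inst.food_group_bounds.items()):
        if gid not in FOOD_GROUPS:
            bad("FoodGroupBound", gid, "unknown food group")
        if b.max_energy_share is not None and gid != "grains":
            bad("FoodGroupBound", gid, "energy-share bound only valid for grains")
        if b.max_g_day is not None and b.min_g_day > b.max_g_day:
            bad("FoodGroupBound", gid, "min exceeds max")

    rp = inst.residual_params
    for fld in ("waste_to_feed_frac", "sludge_use_frac", "sludge_n_frac",
                "sludge_p_frac", "compost_n_loss_frac"):
        val = getattr(rp, fld)
        if not (0.0 <= val <= 1.0):
            bad("ResidualParams", fld, "fraction outside [0, 1]")
    for food, fracs in sorted(rp.stage_waste_fracs.items()):
        for stage, frac in fracs.items():
            if stage not in WASTE_STAGES:
                bad("ResidualParams", food, f"unknown waste stage {stage!r}")
            elif not (0.0 <= frac < 1.0):
                bad("ResidualParams", food, f"waste fraction at {stage!r} outside [0, 1)")
    for crop_id, entry in sorted(rp.tcf.items()):
        if crop_id not in inst.crops:
            bad("ResidualParams", crop_id, "TCF references unknown crop")
            continue
        total = float(entry.get("main_fraction", 0.0))
        for bpid, frac in entry.get("byproducts", {}).items():
            total += float(frac)
            if bpid not in inst.feed_items:
                bad("ResidualParams", crop_id,
                    f"TCF by-product {bpid!r} is not a feed item")
        if total > 1.0 + 1e-9:
            bad("ResidualParams", crop_id, "TCF fractions sum above 1")

    for gtype, fid in sorted(inst.grass_feed_map.items()):
        if gtype not in GRASS_TYPES:
            bad("Instance", gtype, "grass_feed_map key is not a grass land type")
        if fid not in inst.feed_items:
            bad("Instance", gtype, f"grass feed item {fid!r} unresolved")

    for cid, zmap in sorted(inst.current_areas.items()):
        if cid not in inst.crops:
            bad("Instance", cid, "current area for unknown crop")
            continue
        for zid in zmap:
            if zid not in inst.zones:
                bad("Instance", cid, f"current area in unknown zone {zid!r}")

    for k, pop in sorted(inst.population_by_country.items()):
        if pop <= 0:
            bad("Instance", k, "population must be > 0")
        if k not in inst.country_coordinates:
            bad("Instance", k, "country lacks coordinates")

    return v


# ---------------------------------------------------------------------------
# serialization (instances)
# ---------------------------------------------------------------------------

_UNITS_HEADER = {
    "area": "ha",
    "biomass": "t fresh / yr",
    "nutrients": "kg",
    "feed_energy": "MJ",
    "diet": "g fresh / capita / day",
    "emissions": "kg CO2e / yr",
}


def _dc_to_dict(obj: Any) -> Any:
    import numpy as _np

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _dc_to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _dc_to_dict(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_dc_to_dict(v) for v in obj]
    if isinstance(obj, _np.floating):
        return float(obj)
    if isinstance(obj, _np.integer):
        return int(obj)
    return obj


def instance_to_dict(inst: FoodSystemInstance) -> dict[str, Any]:
    d = _dc_to_dict(inst)
    d["units"] = dict(_UNITS_HEADER)
    return d


def _build(cls, data: Mapping[str, Any], where: str):
    _check_keys(cls, data, where)
    return cls(**data)


def instance_from_dict(data: Mapping[str, Any]) -> FoodSystemInstance:
    data = dict(data)
    data.pop("units", None)
    top_known = {f.name for f in dataclasses.fields(FoodSystemInstance)}
    unknown = set(data) - top_known
    if unknown:
        raise InstanceParseError(f"instance: unknown top-level key(s) {sorted(unknown)!r}")

    def build_map(cls, entries: Mapping[str, Mapping], kind: str):
        out = {}
        for key, sub in entries.items():
            sub = dict(sub)
            out[key] = _build(cls, sub, f"{kind}[{key}]")
        return out

    try:
        inst = FoodSystemInstance(
            name=data.get("name", "instance"),
            zones={k: _fix_zone(_build(Zone, v, f"zone[{k}]"))
                   for k, v in data.get("zones", {}).items()},
            crops=build_map(Crop, data.get("crops", {}), "crop"),
            animal_systems=build_map(AnimalSystem, data.get("animal_systems", {}),
                                     "animal_system"),
            feed_items=build_map(FeedItem, data.get("feed_items", {}), "feed_item"),
            fish_stocks=build_map(FishStock, data.get("fish_stocks", {}), "fish_stock"),
            nutrient_specs=build_map(NutrientSpec, data.get("nutrient_specs", {}),
                                     "nutrient_spec"),
            food_group_bounds=build_map(FoodGroupBound,
                                        data.get("food_group_bounds", {}),
                                        "food_group_bound"),
            residual_params=_build(ResidualParams,
                                   data.get("residual_params", {}), "residual_params"),
            emission_constants=_build(EmissionConstants,
                                      data.get("emission_constants", {}),
                                      "emission_constants"),
            population_by_country=dict(data.get("population_by_country", {})),
            country_coordinates={k: tuple(v) for k, v in
                                 data.get("country_coordinates", {}).items()},
            grass_yield=data.get("grass_yield", {}),
            grass_feed_map=dict(data.get("grass_feed_map", {})),
            current_supply_protein=data.get("current_supply_protein", {}),
            current_areas=data.get("current_areas", {}),
            current_artificial_fertilizer_t=float(
                data.get("current_artificial_fertilizer_t", 0.0)),
            current_sludge_t=dict(data.get("current_sludge_t", {})),
            climate_classes=tuple(data.get("climate_classes",
                                           FoodSystemInstance.climate_classes)),
            soil_classes=tuple(data.get("soil_classes",
                                        FoodSystemInstance.soil_classes)),
        )
    except TypeError as exc:  # missing required field
        raise InstanceParseError(str(exc)) from exc

    _check_references(inst)
    return inst


def _fix_zone(z: Zone) -> Zone:
    z.coordinates = tuple(z.coordinates)  # type: ignore[assignment]
    return z


def _check_references(inst: FoodSystemInstance) -> None:
    """Raise DanglingReferenceError on unresolved hard links."""
    for cid, c in inst.crops.items():
        if c.feed_value_id is not None and c.feed_value_id not in inst.feed_items:
            raise DanglingReferenceError(
                f"crop {cid!r} references unknown feed item {c.feed_value_id!r}")
        for zid in c.yield_by_zone:
            if zid not in inst.zones:
                raise DanglingReferenceError(
                    f"crop {cid!r} has a yield for unknown zone {zid!r}")
    for crop_id in inst.residual_params.tcf:
        if crop_id not in inst.crops:
            raise DanglingReferenceError(
                f"TCF entry references unknown crop {crop_id!r}")
    for z in inst.zones.values():
        if z.country_id not in inst.population_by_country:
            raise DanglingReferenceError(
                f"zone {z.zone_id!r} references unknown country {z.country_id!r}")


def write_instance(inst: FoodSystemInstance, path: str | Path) -> None:
    path = Path(path)
    payload = instance_to_dict(inst)
    path.write_text(yaml.safe_dump(payload, sort_keys=True, width=100))


def load_instance(path: str | Path) -> FoodSystemInstance:
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise InstanceParseError(f"{path}: {exc}") from exc
    if not isinstance(data, Mapping):
        raise InstanceParseError(f"{path}: top level must be a mapping")
    return instance_from_dict(data)


# ---------------------------------------------------------------------------
# solutions
# ---------------------------------------------------------------------------

@dataclass
class Solution:
    """One solved scenario: areas, herds, flows, fertilization, diet, GHG."""

    status: str = "optimal"
    objective_value: float = 0.0
    population_multiplier: float = 1.0
    population_fed: float = 0.0
    area: dict[tuple[str, str], float] = field(default_factory=dict)          # (crop, zone) -> ha
    grass_area: dict[tuple[str, str], float] = field(default_factory=dict)    # (zone, type) -> ha
    animals: dict[tuple[str, str], float] = field(default_factory=dict)       # (system, country) -> units
    feed_alloc: dict[tuple[str, str, str], float] = field(default_factory=dict)  # (feed, system, country) -> t
    flows: dict[tuple[str, str, str], float] = field(default_factory=dict)    # (food, origin, dest) -> t
    delivered: dict[tuple[str, str], float] = field(default_factory=dict)     # (food, country) -> t at consumer
    diet: dict[tuple[str, str], float] = field(default_factory=dict)          # (food, country) -> g intake/cap/day
    crop_use: dict[tuple[str, str, str], float] = field(default_factory=dict) # (crop, country, use) -> t
    fertilizer: dict[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)
    # ^ (source, crop, zone) -> (kg N applied, kg P applied)
    byproduct_to_fert: dict[tuple[str, str], float] = field(default_factory=dict)  # (feed, country) -> t
    waste_to_feed_t: dict[str, float] = field(default_factory=dict)           # country -> t
    waste_to_compost_t: dict[str, float] = field(default_factory=dict)
    landings: dict[tuple[str, str], float] = field(default_factory=dict)      # (stock, country) -> t
    ghg: Any | None = None                                                     # GHGInventory
    meta: dict[str, Any] = field(default_factory=dict)
    infeasibility: list[str] = field(default_factory=list)

    def total_land_ha(self) -> float:
        return float(sum(self.area.values()) + sum(self.grass_area.values()))


_SOLUTION_TABLES = {
    # attr -> (filename, key column names, value columns)
    "area": ("area.csv", ["crop", "zone"], ["area_ha"]),
    "grass_area": ("grass_area.csv", ["zone", "land_type"], ["area_ha"]),
    "animals": ("animals.csv", ["system", "country"], ["producing_units"]),
    "feed_alloc": ("feed_alloc.csv", ["feed", "system", "country"], ["t_per_yr"]),
    "flows": ("flows.csv", ["food", "origin", "dest"], ["t_per_yr"]),
    "delivered": ("delivered.csv", ["food", "country"], ["t_per_yr"]),
    "diet": ("diet.csv", ["food", "country"], ["g_per_capita_day"]),
    "crop_use": ("crop_use.csv", ["crop", "country", "use"], ["t_per_yr"]),
    "byproduct_to_fert": ("byproduct_to_fert.csv", ["feed", "country"], ["t_per_yr"]),
    "landings": ("landings.csv", ["stock", "country"], ["t_per_yr"]),
    "waste_to_feed_t": ("waste_to_feed.csv", ["country"], ["t_per_yr"]),
    "waste_to_compost_t": ("waste_to_compost.csv", ["country"], ["t_per_yr"]),
}


def write_solution(sol: Solution, path: str | Path) -> None:
    """Export a solution as deterministic delimited tables under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for attr, (fname, keys, vals) in _SOLUTION_TABLES.items():
        mapping: dict = getattr(sol, attr)
        rows = []
        for key, value in mapping.items():
            key_t = key if isinstance(key, tuple) else (key,)
            rows.append(list(key_t) + [float(value)])
        df = pd.DataFrame(rows, columns=keys + vals)
        df = df.sort_values(keys).reset_index(drop=True) if len(df) else df
        df.to_csv(path / fname, index=False, float_format="%.10g",
                  lineterminator="\n")
    fert_rows = [
        [src, crop, zone, float(n), float(p)]
        for (src, crop, zone), (n, p) in sol.fertilizer.items()
    ]
    fert = pd.DataFrame(fert_rows, columns=["source", "crop", "zone",
                                            "n_kg_per_yr", "p_kg_per_yr"])
    if len(fert):
        fert = fert.sort_values(["source", "crop", "zone"]).reset_index(drop=True)
    fert.to_csv(path / "fertilizer.csv", index=False, float_format="%.10g",
                lineterminator="\n")
    summary = pd.DataFrame(
        [
            ["status", sol.status],
            ["objective_value", repr(float(sol.objective_value))],
            ["population_multiplier", repr(float(sol.population_multiplier))],
            ["population_fed", repr(float(sol.population_fed))],
        ],
        columns=["key", "value"],
    )
    summary.to_csv(path / "summary.csv", index=False, lineterminator="\n")


def read_solution(path: str | Path) -> Solution:
    path = Path(path)
    sol = Solution()
    for attr, (fname, keys, vals) in _SOLUTION_TABLES.items():
        df = pd.read_csv(path / fname)
        mapping = {}
        for _, row in df.iterrows():
            key = tuple(str(row[k]) for k in keys)
            mapping[key if len(key) > 1 else key[0]] = float(row[vals[0]])
        setattr(sol, attr, mapping)
    fert = pd.read_csv(path / "fertilizer.csv")
    sol.fertilizer = {
        (str(r["source"]), str(r["crop"]), str(r["zone"])):
            (float(r["n_kg_per_yr"]), float(r["p_kg_per_yr"]))
        for _, r in fert.iterrows()
    }
    summary = pd.read_csv(path / "summary.csv")
    kv = dict(zip(summary["key"], summary["value"]))
    sol.status = str(kv["status"])
    sol.objective_value = float(kv["objective_value"])
    sol.population_multiplier = float(kv["population_multiplier"])
    sol.population_fed = float(kv["population_fed"])
    return sol
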