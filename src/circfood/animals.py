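"""Livestock and aquaculture herd coupling, rations, manure; capture fisheries.

A producing animal (e.g. a fattening pig, a dairy cow) drags its whole life
cycle along: parent and reproduction stock are coupled to the producing herd
by fixed ratios, and a unit of product can only be made when the nutritional
requirements of all stock classes are met within their feed intake capacity.
Requirements scale linearly with output (fixed productivity-requirement
relation per level).

Manure follows a mass balance: excretion = intake - retention, split between
the manure management system (MMS, exportable as fertilizer) and direct
deposition on grassland by grazing ruminants. Capture fisheries are capped at
maximum sustainable yield (MSY) per stock; landings split into edible food
and feed-grade by-products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from .instance import AnimalSystem, FeedItem, FishStock

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StockRequirements:
    producing_units: float
    parent_units: float
    repro_units: float
    requirements: dict[str, float]      # feed nutrient -> total amount / yr
    intake_capacity_t_dm: float         # total t DM / yr


def stock_requirements(target_output_t: float, system: AnimalSystem
                       ) -> StockRequirements:
    """Total herd requirements to produce ``target_output_t`` of product.

    Auxiliary (parent + reproduction) animals are coupled by fixed ratios;
    requirements and intake capacities are summed over all stock classes and
    are linear in the target output.
    """
    if target_output_t < 0:
        raise ValueError("target output must be >= 0")
    producing = target_output_t / system.output_t_per_unit
    parent = producing * system.parent_stock_ratio
    repro = producing * system.repro_stock_ratio
    aux = parent + repro

    req: dict[str, float] = {}
    for nut, per_t in system.requirement_per_t_product.items():
        req[nut] = target_output_t * per_t
    for nut, per_unit in system.aux_requirement_per_unit.items():
        req[nut] = req.get(nut, 0.0) + aux * per_unit

    capacity = (producing * system.intake_capacity_t_dm
                + aux * system.aux_intake_capacity_t_dm)
    return StockRequirements(producing, parent, repro, req, capacity)


@dataclass(frozen=True)
class RationFinding:
    kind: str      # "illegal_item" | "nutrient_deficit" | "intake_capacity"
    detail: str


def ration_check(
    ration: Mapping[str, float],
    system: AnimalSystem,
    stocks: StockRequirements,
    feed_items: Mapping[str, FeedItem],
) -> list[RationFinding]:
    """Feasibility of a realized ration for a herd.

    Feasible (empty list) iff every item is legal for the species, the summed
    nutrient delivery covers every tracked requirement, and total dry matter
    fits within the herd intake capacity. Fish systems are evaluated with the
    fish-specific feed composition.
    """
    findings: list[RationFinding] = []
    delivery: dict[str, float] = {n: 0.0 for n in stocks.requirements}
    dm = 0.0
    for fid in sorted(ration):
        t = float(ration[fid])
        if t < 0:
            raise ValueError(f"negative ration amount for {fid!r}")
        if fid not in feed_items:
            raise KeyError(f"unknown feed item {fid!r}")
        item = feed_items[fid]
        if not item.legal_for(system.species):
            findings.append(RationFinding(
                "illegal_item",
                f"{fid} is not allowed for species {system.species}"))
            continue
        comp = item.comp_for(system.species)
        dm += t * comp.get("dm_frac", 0.0)
        for nut in delivery:
            delivery[nut] += t * comp.get(nut, 0.0)

    for nut, need in sorted(stocks.requirements.items()):
        if delivery.get(nut, 0.0) < need - 1e-9 * max(1.0, need):
            findings.append(RationFinding(
                "nutrient_deficit",
                f"{nut}: delivered {delivery.get(nut, 0.0):.6g} < required {need:.6g}"))
    if dm > stocks.intake_capacity_t_dm + 1e-9 * max(1.0, stocks.intake_capacity_t_dm):
        findings.append(RationFinding(
            "intake_capacity",
            f"dry matter {dm:.6g} t exceeds capacity "
            f"{stocks.intake_capacity_t_dm:.6g} t"))
    return findings


def animal_outputs(producing_units: float, system: AnimalSystem
                   ) -> tuple[float, dict[str, float]]:
    """(t product / yr, total nutrient content of the product)."""
    if producing_units < 0:
        raise ValueError("producing units must be >= 0")
    product_t = producing_units * system.output_t_per_unit
    grams = product_t * 1e6
    totals = {n: grams * c for n, c in system.product_composition.items()}
    return product_t, totals


@dataclass(frozen=True)
class ManureSplit:
    n_to_mms_kg: float
    p_to_mms_kg: float
    n_on_grassland_kg: float
    p_on_grassland_kg: float
    vs_kg: float


def manure_excretion(
    n_intake_kg: float,
    p_intake_kg: float,
    n_retention_frac: float,
    p_retention_frac: float,
    grazing_share: float,
    vs_kg: float = 0.0,
) -> ManureSplit:
    """Excretion = intake x (1 - retention), split MMS vs grassland.

    ``grazing_share`` is the fraction of excretion deposited directly on
    grassland by grazing ruminants (zero for housed or monogastric animals).
    Volatile solids (``vs_kg``) are computed by the caller from the realized
    ration's digestibilities and split with the same share.
    """
    for name, frac in (("n_retention_frac", n_retention_frac),
                       ("p_retention_frac", p_retention_frac),
                       ("grazing_share", grazing_share)):
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    n_ex = n_intake_kg * (1.0 - n_retention_frac)
    p_ex = p_intake_kg * (1.0 - p_retention_frac)
    return ManureSplit(
        n_to_mms_kg=n_ex * (1.0 - grazing_share),
        p_to_mms_kg=p_ex * (1.0 - grazing_share),
        n_on_grassland_kg=n_ex * grazing_share,
        p_on_grassland_kg=p_ex * grazing_share,
        vs_kg=vs_kg,
    )


def ration_volatile_solids(
    ration: Mapping[str, float],
    species: str,
    feed_items: Mapping[str, FeedItem],
    ash_frac: float = 0.08,
) -> float:
    """Volatile solid excretion (kg/yr) from the digestibility of the ration.

    The indigestible organic-matter fraction of feed dry matter is excreted
    as volatile solids: VS = sum_f t_f x DM_f x (1 - dOM_f) x (1 - ash).
    """
    vs_t = 0.0
    for fid, t in ration.items():
        comp = feed_items[fid].comp_for(species)
        vs_t += t * comp.get("dm_frac", 0.0) * (1.0 - comp.get("dig_om_frac", 0.0))
    return vs_t * (1.0 - ash_frac) * 1000.0


def fishery_supply(
    quotas: Mapping[tuple[str, str], float],
    stocks: Mapping[str, FishStock],
) -> dict[tuple[str, str], tuple[float, float]]:
    """Edible fish and feed-grade by-products from capture-fishery quotas.

    ``quotas`` maps (stock, country) to requested landings (t/yr). Landings
    are clipped to the stock's MSY cap for the country (with a warning);
    edible food = landings x edible_frac, the remainder becomes feed-eligible
    by-product. Returns (stock, country) -> (edible t, by-product t).
    """
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for (stock_id, country), wanted in sorted(quotas.items()):
        if wanted < 0:
            raise ValueError("quota must be >= 0")
        stock = stocks[stock_id]
        cap = float(stock.msy_cap_t.get(country, 0.0))
        landed = min(float(wanted), cap)
        if wanted > cap + 1e-12:
            logger.warning(
                "requested landings %.6g t exceed MSY cap %.6g t for %s in %s; clipped",
                wanted, cap, stock_id, country)
        edible = landed * stock.edible_frac
        out[(stock_id, country)] = (edible, landed - edible)
    return out
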