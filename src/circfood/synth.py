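"""Synthetic food-system instance generation.

Real studies of this kind are parameterized from crop statistics, food
balance sheets, feed tables, food-composition databases and fertilizer
statistics. None of those are shipped here; this module generates
self-consistent instances that emulate their statistical structure:

* multi-zone yield heterogeneity (lognormal zone multipliers around crop
  means, sigma 0.3 by default — strictly positive and right-skewed like
  observed yield data);
* per-food-group composition anchors with jitter, so nutrient feasibility
  is achievable without real composition data; vitamin B12 and the other
  animal-source-only nutrients are zero in every plant food;
* technical conversion factors, stage-wise waste fractions in (0, 0.3),
  herd-coupled animal systems with parent/reproduction stock, MSY-capped
  fisheries;
* a consistent "current" baseline (diet, areas, fodder production, grass
  use, artificial fertilizer, sludge) constructed so the calibration
  scenario is feasible by construction.

The generator also builds tiny instances with analytically known optima
(strict-dominance construction) and crop-only instances small enough for
exhaustive grid-search oracles.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .instance import (
    AnimalSystem,
    Crop,
    EmissionConstants,
    FeedItem,
    FishStock,
    FoodGroupBound,
    FoodSystemInstance,
    NutrientSpec,
    ResidualParams,
    Zone,
    validate_instance,
)
from .nutrients import (
    EAT_LANCET_BOUNDS_G_DAY,
    FODDER_GROUP,
    FOOD_GROUPS,
    GRAINS_MAX_ENERGY_SHARE,
    NUTRIENT_UNITS,
    NUTRIENTS,
    RUMINANT_SPECIES,
)

_DAYS = 365.0


class GenerationError(RuntimeError):
    """A size/seed combination cannot satisfy the feasibility requirements."""


# ---------------------------------------------------------------------------
# anchor tables (plausible per-food-group values; per g fresh)
# ---------------------------------------------------------------------------

PLANT_GROUPS = ("grains", "tubers", "vegetables", "fruit", "legumes",
                "nuts_seeds", "oil_fat", "sugar", "other")

#: agronomic anchors: yield t/ha, rotation frequency, residue ratio,
#: N/P concentrations kg/t (product, residue), TCF main fraction,
#: by-product feed item and mass fraction.
_GROUP_AGRO: dict[str, dict] = {
    "grains":     dict(yield_t=5.5, rot=0.5, rrr=1.0, n_p=18.0, p_p=3.5,
                       n_r=6.0, p_r=1.0, main=0.75, bp=("bran", 0.22),
                       feed="grain_feed"),
    "tubers":     dict(yield_t=35.0, rot=1 / 3, rrr=0.2, n_p=3.2, p_p=0.6,
                       n_r=1.5, p_r=0.3, main=0.95, bp=None, feed=None),
    "vegetables": dict(yield_t=25.0, rot=1 / 3, rrr=0.3, n_p=2.5, p_p=0.5,
                       n_r=2.0, p_r=0.4, main=0.90, bp=None, feed=None),
    "fruit":      dict(yield_t=15.0, rot=1.0, rrr=0.1, n_p=1.5, p_p=0.3,
                       n_r=1.0, p_r=0.2, main=0.92, bp=None, feed=None),
    "legumes":    dict(yield_t=3.0, rot=0.25, rrr=1.2, n_p=35.0, p_p=4.5,
                       n_r=12.0, p_r=1.0, main=0.88, bp=None, feed=None),
    "nuts_seeds": dict(yield_t=2.5, rot=1.0, rrr=0.5, n_p=28.0, p_p=4.0,
                       n_r=6.0, p_r=0.8, main=0.45, bp=None, feed=None),
    "oil_fat":    dict(yield_t=3.0, rot=1 / 6, rrr=1.5, n_p=34.0, p_p=6.0,
                       n_r=7.0, p_r=1.0, main=0.40, bp=("oil_meal", 0.55),
                       feed=None),
    "sugar":      dict(yield_t=70.0, rot=0.25, rrr=0.4, n_p=1.8, p_p=0.4,
                       n_r=2.5, p_r=0.3, main=0.16, bp=("beet_pulp", 0.25),
                       feed=None),
    "other":      dict(yield_t=10.0, rot=1 / 3, rrr=0.3, n_p=4.0, p_p=0.8,
                       n_r=2.0, p_r=0.3, main=0.85, bp=None, feed=None),
}

_FODDER_AGRO: dict[str, dict] = {
    "fodder_maize":  dict(yield_t=40.0, rot=0.5, n_p=3.8, p_p=0.7,
                          feed="fodder_maize_feed"),
    "fodder_clover": dict(yield_t=35.0, rot=0.5, n_p=5.5, p_p=0.6,
                          feed="fodder_clover_feed"),
    "fodder_legume": dict(yield_t=3.5, rot=1 / 3, n_p=40.0, p_p=4.5,
                          feed="fodder_legume_feed"),
}

#: food composition anchors per group (per g fresh, units per NUTRIENT_UNITS)
_GROUP_COMP: dict[str, dict[str, float]] = {
    "grains": dict(energy=3.5, protein=0.12, fat_total=0.02, saturated_fat=0.004,
                   carbohydrates=0.72, fibre=0.11, linoleic_acid=0.008,
                   alpha_linolenic_acid=0.0006, sodium=0.02, potassium=3.6,
                   calcium=0.34, phosphorus=3.5, magnesium=1.2, iron=0.035,
                   copper=0.004, selenium=0.7, zinc=0.026, vitamin_b1=0.004,
                   vitamin_b2=0.001, vitamin_b3=0.05, vitamin_b6=0.003,
                   vitamin_b9=0.4, vitamin_e=0.01, vitamin_k=0.02),
    "tubers": dict(energy=0.8, protein=0.02, fat_total=0.001, carbohydrates=0.17,
                   fibre=0.022, sodium=0.06, potassium=4.2, calcium=0.12,
                   phosphorus=0.57, magnesium=0.23, iron=0.008, copper=0.001,
                   selenium=0.04, zinc=0.003, vitamin_b1=0.0008,
                   vitamin_b3=0.011, vitamin_b6=0.003, vitamin_b9=0.15,
                   vitamin_c=0.2),
    "vegetables": dict(energy=0.3, protein=0.018, fat_total=0.002,
                       carbohydrates=0.05, fibre=0.025, sodium=0.3,
                       potassium=2.9, calcium=0.4, phosphorus=0.4,
                       magnesium=0.2, iron=0.01, copper=0.001, selenium=0.05,
                       zinc=0.004, iodine=0.02, vitamin_a=1.5, vitamin_b2=0.001,
                       vitamin_b9=0.5, vitamin_c=0.3, vitamin_e=0.005,
                       vitamin_k=0.8),
    "fruit": dict(energy=0.55, protein=0.007, fat_total=0.002,
                  carbohydrates=0.13, fibre=0.022, potassium=1.7, calcium=0.1,
                  magnesium=0.1, iron=0.003, vitamin_a=0.3, vitamin_b9=0.1,
                  vitamin_c=0.3, vitamin_e=0.003),
    "legumes": dict(energy=3.4, protein=0.22, fat_total=0.015,
                    carbohydrates=0.60, fibre=0.16, potassium=13.0, calcium=0.9,
                    phosphorus=3.7, magnesium=1.7, iron=0.06, copper=0.008,
                    selenium=0.8, zinc=0.03, vitamin_b1=0.007, vitamin_b3=0.02,
                    vitamin_b6=0.004, vitamin_b9=4.0, vitamin_e=0.001),
    "nuts_seeds": dict(energy=6.0, protein=0.18, fat_total=0.50,
                       saturated_fat=0.06, linoleic_acid=0.12,
                       alpha_linolenic_acid=0.02, carbohydrates=0.20,
                       fibre=0.08, potassium=6.5, calcium=1.0, phosphorus=4.7,
                       magnesium=2.6, iron=0.04, copper=0.013, selenium=0.5,
                       zinc=0.03, vitamin_b1=0.005, vitamin_b3=0.01,
                       vitamin_b6=0.004, vitamin_b9=0.6, vitamin_e=0.2),
    "oil_fat": dict(energy=8.8, fat_total=0.99, saturated_fat=0.08,
                    linoleic_acid=0.25, alpha_linolenic_acid=0.09,
                    vitamin_e=0.4, vitamin_k=0.7),
    "sugar": dict(energy=3.9, carbohydrates=0.998),
    "other": dict(energy=1.5, protein=0.04, fat_total=0.03, carbohydrates=0.25,
                  fibre=0.04, potassium=2.0, calcium=0.3, iron=0.01,
                  magnesium=0.3, vitamin_c=0.05),
}

_ANIMAL_COMP: dict[str, dict[str, float]] = {
    "dairy": dict(energy=0.64, protein=0.034, fat_total=0.037,
                  saturated_fat=0.023, carbohydrates=0.048, cholesterol=0.14,
                  sodium=0.4, potassium=1.5, calcium=1.2, phosphorus=0.93,
                  magnesium=0.1, zinc=0.004, selenium=0.037, iodine=0.23,
                  vitamin_a=0.46, vitamin_b1=0.0005, vitamin_b2=0.0017,
                  vitamin_b3=0.001, vitamin_b6=0.0004, vitamin_b9=0.05,
                  vitamin_b12=0.0045, vitamin_d=0.0013, vitamin_e=0.0007),
    "beef": dict(energy=2.5, protein=0.19, fat_total=0.20, saturated_fat=0.08,
                 cholesterol=0.7, sodium=0.6, potassium=3.0, calcium=0.1,
                 phosphorus=1.8, magnesium=0.2, iron=0.021, zinc=0.045,
                 selenium=0.2, vitamin_b2=0.002, vitamin_b3=0.04,
                 vitamin_b6=0.003, vitamin_b9=0.06, vitamin_b12=0.025,
                 vitamin_d=0.001),
    "pig": dict(energy=2.6, protein=0.17, fat_total=0.22, saturated_fat=0.08,
                cholesterol=0.7, sodium=0.6, potassium=3.0, phosphorus=1.8,
                iron=0.009, zinc=0.022, selenium=0.3, vitamin_b1=0.006,
                vitamin_b2=0.002, vitamin_b3=0.04, vitamin_b6=0.003,
                vitamin_b12=0.007, vitamin_d=0.005),
    "broiler": dict(energy=1.7, protein=0.19, fat_total=0.11,
                    saturated_fat=0.03, cholesterol=0.75, sodium=0.7,
                    potassium=2.2, phosphorus=1.7, iron=0.009, zinc=0.013,
                    selenium=0.15, vitamin_b3=0.08, vitamin_b6=0.004,
                    vitamin_b12=0.004, vitamin_d=0.002),
    "layer": dict(energy=1.4, protein=0.125, fat_total=0.10,
                  saturated_fat=0.03, cholesterol=3.7, sodium=1.4,
                  potassium=1.4, calcium=0.5, phosphorus=1.9, iron=0.017,
                  zinc=0.011, selenium=0.3, iodine=0.5, vitamin_a=1.6,
                  vitamin_b2=0.005, vitamin_b9=0.5, vitamin_b12=0.011,
                  vitamin_d=0.02, vitamin_e=0.01),
    "salmon": dict(energy=2.0, protein=0.20, fat_total=0.13,
                   saturated_fat=0.03, dha=1.4, epa=0.9, cholesterol=0.6,
                   potassium=3.6, phosphorus=2.4, selenium=0.36, iodine=0.1,
                   vitamin_b3=0.08, vitamin_b6=0.006, vitamin_b12=0.03,
                   vitamin_d=0.11, vitamin_e=0.035),
    "tilapia": dict(energy=1.0, protein=0.20, fat_total=0.02, dha=0.1,
                    epa=0.05, cholesterol=0.5, potassium=3.0, phosphorus=1.7,
                    selenium=0.4, vitamin_b3=0.04, vitamin_b12=0.016,
                    vitamin_d=0.03),
}

_WILD_FISH_COMP = dict(energy=1.5, protein=0.19, fat_total=0.08, dha=0.8,
                       epa=0.5, cholesterol=0.55, potassium=3.3,
                       phosphorus=2.0, selenium=0.35, iodine=0.3,
                       vitamin_b3=0.05, vitamin_b12=0.02, vitamin_d=0.07)

#: essential-amino-acid shares of protein
_AA_SHARES_PLANT = dict(histidine=0.027, isoleucine=0.045, leucine=0.079,
                        lysine=0.038, methionine=0.020, phenylalanine=0.050,
                        threonine=0.038, tryptophan=0.012, valine=0.051)
_AA_SHARES_ANIMAL = dict(histidine=0.032, isoleucine=0.050, leucine=0.085,
                         lysine=0.082, methionine=0.028, phenylalanine=0.045,
                         threonine=0.044, tryptophan=0.013, valine=0.053)

#: livestock feed compositions (per t fresh)
_FEED_TABLE: dict[str, dict] = {
    "grain_feed": dict(origin="fodder_crop", dm=0.87, energy=12000.0,
                       prot=90.0, dig_om=0.85, n=19.0, p=3.5),
    "fodder_maize_feed": dict(origin="fodder_crop", dm=0.35, energy=3800.0,
                              prot=25.0, dig_om=0.72, n=3.8, p=0.7),
    "fodder_clover_feed": dict(origin="fodder_crop", dm=0.20, energy=2000.0,
                               prot=35.0, dig_om=0.70, n=5.5, p=0.6),
    "fodder_legume_feed": dict(origin="fodder_crop", dm=0.87, energy=11800.0,
                               prot=230.0, dig_om=0.86, n=40.0, p=4.5),
    "grass_temporary": dict(origin="grass", dm=0.20, energy=2100.0,
                            prot=30.0, dig_om=0.72, n=6.0, p=0.7),
    "grass_permanent": dict(origin="grass", dm=0.20, energy=2100.0,
                            prot=30.0, dig_om=0.70, n=6.0, p=0.7),
    "grass_rangeland": dict(origin="grass", dm=0.22, energy=1800.0,
                            prot=24.0, dig_om=0.62, n=5.0, p=0.6),
    "bran": dict(origin="crop_byproduct", dm=0.88, energy=9800.0, prot=120.0,
                 dig_om=0.70, n=25.0, p=10.0),
    "oil_meal": dict(origin="crop_byproduct", dm=0.89, energy=10500.0,
                     prot=380.0, dig_om=0.78, n=55.0, p=11.0),
    "beet_pulp": dict(origin="crop_byproduct", dm=0.25, energy=2800.0,
                      prot=20.0, dig_om=0.85, n=3.5, p=0.25),
    "animal_meal": dict(origin="animal_byproduct", dm=0.95, energy=14000.0,
                        prot=500.0, dig_om=0.85, n=90.0, p=25.0),
    "fish_meal": dict(origin="fish_byproduct", dm=0.92, energy=13500.0,
                      prot=520.0, dig_om=0.88, n=95.0, p=25.0),
    "food_waste": dict(origin="food_waste", dm=0.25, energy=3000.0, prot=30.0,
                       dig_om=0.80, n=5.0, p=0.8),
}

#: species parameter table; requirements per t product, aux per animal-year
_SPECIES_TABLE: dict[str, dict] = {
    "dairy":   dict(output=8.0, energy=5000.0, prot=55.0, intake=6.0,
                    parent=0.0, repro=0.3, aux_energy=25000.0, aux_prot=300.0,
                    aux_intake=3.5, n_ret=0.25, p_ret=0.30, bp_frac=0.02,
                    mms=dict(MCF=0.17, B0=0.24, n2o_ef_direct=0.005,
                             volatilization_frac=0.25, leaching_frac=0.0),
                    ym=6.0, grazing=True),
    "pig":     dict(output=0.09, energy=36000.0, prot=333.0, intake=0.30,
                    parent=0.04, repro=0.0, aux_energy=14000.0, aux_prot=150.0,
                    aux_intake=1.2, n_ret=0.30, p_ret=0.35, bp_frac=0.12,
                    mms=dict(MCF=0.35, B0=0.45, n2o_ef_direct=0.003,
                             volatilization_frac=0.30, leaching_frac=0.0),
                    ym=None, grazing=False),
    "broiler": dict(output=0.01, energy=26000.0, prot=330.0, intake=0.02,
                    parent=0.008, repro=0.0, aux_energy=550.0, aux_prot=9.0,
                    aux_intake=0.045, n_ret=0.35, p_ret=0.40, bp_frac=0.10,
                    mms=dict(MCF=0.015, B0=0.39, n2o_ef_direct=0.001,
                             volatilization_frac=0.30, leaching_frac=0.0),
                    ym=None, grazing=False),
    "layer":   dict(output=0.02, energy=27000.0, prot=340.0, intake=0.045,
                    parent=0.01, repro=0.0, aux_energy=550.0, aux_prot=9.0,
                    aux_intake=0.045, n_ret=0.30, p_ret=0.35, bp_frac=0.0,
                    mms=dict(MCF=0.015, B0=0.39, n2o_ef_direct=0.001,
                             volatilization_frac=0.30, leaching_frac=0.0),
                    ym=None, grazing=False),
    "beef":    dict(output=0.30, energy=83000.0, prot=1100.0, intake=2.5,
                    parent=1.0, repro=0.0, aux_energy=30000.0, aux_prot=300.0,
                    aux_intake=5.0, n_ret=0.10, p_ret=0.15, bp_frac=0.15,
                    mms=dict(MCF=0.02, B0=0.24, n2o_ef_direct=0.01,
                             volatilization_frac=0.25, leaching_frac=0.0),
                    ym=6.5, grazing=True),
    "salmon":  dict(output=1.0, energy=18000.0, prot=330.0, intake=1.3,
                    parent=0.0, repro=0.0, aux_energy=0.0, aux_prot=0.0,
                    aux_intake=0.0, n_ret=0.40, p_ret=0.40, bp_frac=0.05,
                    mms=dict(), ym=None, grazing=False),
    "tilapia": dict(output=1.0, energy=14000.0, prot=280.0, intake=1.4,
                    parent=0.0, repro=0.0, aux_energy=0.0, aux_prot=0.0,
                    aux_intake=0.0, n_ret=0.38, p_ret=0.38, bp_frac=0.05,
                    mms=dict(), ym=None, grazing=False),
}

_SPECIES_ORDER = ("dairy", "pig", "broiler", "layer", "beef", "salmon", "tilapia")

#: current (baseline) supply per food group, g fresh / capita / day
_CURRENT_SUPPLY_G_DAY: dict[str, float] = {
    "grains": 250.0, "tubers": 150.0, "vegetables": 180.0, "fruit": 120.0,
    "legumes": 20.0, "nuts_seeds": 10.0, "oil_fat": 30.0, "sugar": 40.0,
    "other": 20.0, "dairy": 400.0, "red_meat": 70.0, "chicken": 60.0,
    "eggs": 30.0, "fish": 25.0,
}

#: reference healthy intake used to anchor the per-nutrient bounds,
#: g fresh / capita / day (within the food-group guardrails)
_REFERENCE_INTAKE_G_DAY: dict[str, float] = {
    "grains": 200.0, "tubers": 80.0, "vegetables": 300.0, "fruit": 150.0,
    "legumes": 60.0, "nuts_seeds": 25.0, "oil_fat": 25.0, "sugar": 20.0,
    "other": 20.0, "dairy": 250.0, "red_meat": 14.0, "chicken": 25.0,
    "eggs": 12.0, "fish": 25.0,
}

#: nutrients given a minimum bound, as a factor of the reference intake
_MIN_FACTORS: dict[str, float] = {
    "energy": 0.80, "protein": 0.80, "fibre": 0.70, "calcium": 0.70,
    "iron": 0.70, "zinc": 0.70, "magnesium": 0.70, "potassium": 0.70,
    "selenium": 0.60, "iodine": 0.50, "vitamin_a": 0.60, "vitamin_b1": 0.60,
    "vitamin_b2": 0.60, "vitamin_b3": 0.60, "vitamin_b6": 0.60,
    "vitamin_b9": 0.60, "vitamin_b12": 0.60, "vitamin_c": 0.60,
    "vitamin_d": 0.50, "vitamin_e": 0.60, "dha": 0.50, "epa": 0.50,
    "linoleic_acid": 0.50, "alpha_linolenic_acid": 0.50,
    "histidine": 0.70, "isoleucine": 0.70, "leucine": 0.70, "lysine": 0.70,
    "methionine": 0.70, "phenylalanine": 0.70, "threonine": 0.70,
    "tryptophan": 0.70, "valine": 0.70,
}

#: nutrients given a maximum bound, as a factor of the reference intake
_MAX_FACTORS: dict[str, float] = {
    "energy": 1.30, "fresh_weight": 2.00, "sodium": 4.00, "cholesterol": 2.00,
    "saturated_fat": 3.00, "fat_total": 3.00, "sugar": 0.0,  # placeholder
}


def _complete_composition(base: dict[str, float], protein: float,
                          animal: bool, rng: np.random.Generator,
                          jitter: float = 0.10) -> dict[str, float]:
    shares = _AA_SHARES_ANIMAL if animal else _AA_SHARES_PLANT
    out = {n: 0.0 for n in NUTRIENTS}
    out.update({k: float(v) for k, v in base.items()})
    out["fresh_weight"] = 1.0
    for aa, share in shares.items():
        out[aa] = protein * share
    for n in NUTRIENTS:
        if n == "fresh_weight" or out[n] == 0.0:
            continue
        out[n] = float(out[n] * rng.lognormal(0.0, jitter))
    return out


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_instance(
    n_zones: int = 3,
    n_countries: int = 2,
    n_crops: int = 10,
    n_animal_systems: int = 4,
    seed: int = 1,
    yield_sigma: float = 0.3,
    population_per_country: float = 4e6,
) -> FoodSystemInstance:
    """Generate a self-consistent instance; deterministic for a fixed seed.

    ``n_crops`` counts food crops (at least one per plant food group, so a
    minimum of 9); three fodder crops are always added as the feed backbone.
    Raises :class:`GenerationError` when the requested sizes cannot satisfy
    the structural requirements.
    """
    if min(n_zones, n_countries, n_crops, n_animal_systems) < 1:
        raise GenerationError("all sizes must be >= 1")
    if n_crops < len(PLANT_GROUPS):
        raise GenerationError(
            f"need at least {len(PLANT_GROUPS)} food crops to cover every "
            "plant food group")
    if n_zones < n_countries:
        raise GenerationError("need at least one zone per country")

    rng = np.random.default_rng(seed)
    countries = [f"C{i + 1}" for i in range(n_countries)]
    population = {k: float(population_per_country * rng.uniform(0.8, 1.2))
                  for k in countries}
    coords = {k: (600.0 * i, 0.0) for i, k in enumerate(countries)}

    # zone skeleton: country assignment round-robin, lognormal size weights
    zone_ids = [f"Z{i + 1}" for i in range(n_zones)]
    zone_country = {z: countries[i % n_countries] for i, z in enumerate(zone_ids)}
    zone_weight = {z: float(rng.lognormal(0.0, 0.4)) for z in zone_ids}
    climates = ["temperate_wet", "temperate_dry", "boreal_wet", "boreal_dry"]
    soils = ["clay", "other", "sand", "organic"]
    zone_climate = {z: climates[i % len(climates)] for i, z in enumerate(zone_ids)}
    zone_soil = {z: soils[i % len(soils)] for i, z in enumerate(zone_ids)}

    # crops: one per plant group, extras cycle through the groups; fodder
    # backbone always present
    crop_groups: list[tuple[str, str]] = []
    for i in range(n_crops):
        g = PLANT_GROUPS[i % len(PLANT_GROUPS)]
        idx = i // len(PLANT_GROUPS) + 1
        crop_groups.append((f"{g}_{idx}", g))
    crops: dict[str, Crop] = {}
    for cid, g in crop_groups:
        agro = _GROUP_AGRO[g]
        mean_y = agro["yield_t"] * rng.lognormal(0.0, 0.1)
        yields = {z: float(mean_y * rng.lognormal(0.0, yield_sigma))
                  for z in zone_ids}
        base = dict(_GROUP_COMP[g])
        comp = _complete_composition(base, base.get("protein", 0.0), False, rng)
        crops[cid] = Crop(
            crop_id=cid, food_group=g, yield_by_zone=yields,
            rotation_max_frequency=agro["rot"],
            residue_to_product_ratio=agro["rrr"],
            n_conc_product=agro["n_p"], p_conc_product=agro["p_p"],
            n_conc_residue=agro["n_r"], p_conc_residue=agro["p_r"],
            food_composition=comp,
            feed_value_id=agro["feed"],
        )
    for fid, agro in _FODDER_AGRO.items():
        mean_y = agro["yield_t"]
        crops[fid] = Crop(
            crop_id=fid, food_group=FODDER_GROUP,
            yield_by_zone={z: float(mean_y * rng.lognormal(0.0, yield_sigma))
                           for z in zone_ids},
            rotation_max_frequency=agro["rot"],
            n_conc_product=agro["n_p"], p_conc_product=agro["p_p"],
            feed_value_id=agro["feed"],
        )

    # feed items
    feed_items: dict[str, FeedItem] = {}
    for fid, row in _FEED_TABLE.items():
        comp = {
            "dm_frac": row["dm"], "energy_mj_per_t": row["energy"],
            "dig_protein_kg_per_t": row["prot"],
            "gross_energy_mj_per_t": row["dm"] * 18400.0,
            "dig_om_frac": row["dig_om"], "n_kg_per_t": row["n"],
            "p_kg_per_t": row["p"],
        }
        legality: dict[str, bool] = {}
        if row["origin"] == "grass":
            legality = {sp: sp in RUMINANT_SPECIES for sp in _SPECIES_ORDER}
        elif row["origin"] in ("food_waste", "animal_byproduct",
                               "fish_byproduct"):
            legality = {sp: sp not in RUMINANT_SPECIES for sp in _SPECIES_ORDER}
        feed_items[fid] = FeedItem(
            feed_id=fid, origin=row["origin"], comp_livestock=comp,
            comp_fish=dict(comp), legality=legality,
            wet=row["origin"] == "food_waste")

    # animal systems
    if n_animal_systems > len(_SPECIES_ORDER) * 3:
        raise GenerationError("too many animal systems requested")
    levels = ("high", "medium", "low")
    systems: dict[str, AnimalSystem] = {}
    for i in range(n_animal_systems):
        sp = _SPECIES_ORDER[i % len(_SPECIES_ORDER)]
        level = levels[i // len(_SPECIES_ORDER)]
        factor = {"high": 1.0, "medium": 1.15, "low": 1.3}[level]
        row = _SPECIES_TABLE[sp]
        is_fish = sp in ("salmon", "tilapia")
        sid = f"{sp}_{level}" if level != "high" else sp
        comp = _complete_composition(
            dict(_ANIMAL_COMP[sp]), _ANIMAL_COMP[sp].get("protein", 0.0),
            True, rng)
        systems[sid] = AnimalSystem(
            system_id=sid, species=sp,
            productivity_level="single" if is_fish else level,
            output_t_per_unit=row["output"],
            requirement_per_t_product={
                "energy_mj_per_t": row["energy"] * factor,
                "dig_protein_kg_per_t": row["prot"] * factor,
            },
            intake_capacity_t_dm=row["intake"],
            parent_stock_ratio=row["parent"],
            repro_stock_ratio=row["repro"],
            aux_requirement_per_unit={
                "energy_mj_per_t": row["aux_energy"],
                "dig_protein_kg_per_t": row["aux_prot"],
            },
            aux_intake_capacity_t_dm=row["aux_intake"],
            product_composition=comp,
            n_retention_frac=row["n_ret"], p_retention_frac=row["p_ret"],
            byproduct_frac=row["bp_frac"], mms_params=dict(row["mms"]),
            ym_percent=row["ym"], grazing_allowed=row["grazing"],
        )

    # fish stocks (capture fisheries), MSY ~ 25 kg/capita/yr
    fish_stocks = {
        "atlantic_mix": FishStock(
            stock_id="atlantic_mix", species="wild_mix",
            msy_cap_t={k: 0.025 * population[k] for k in countries},
            edible_frac=0.55,
            food_composition=_complete_composition(
                dict(_WILD_FISH_COMP), _WILD_FISH_COMP["protein"], True, rng),
            n_conc_product=_WILD_FISH_COMP["protein"] * 1000.0 / 6.25,
            p_conc_product=4.0,
        )
    }

    # stage waste fractions per food commodity
    foods = sorted(c for c, cr in crops.items() if cr.is_food_crop)
    foods += sorted(s.food_id for s in systems.values())
    foods.append("wild_fish")
    stage_fracs = {
        f: {
            "post_harvest": float(rng.uniform(0.02, 0.08)),
            "processing": float(rng.uniform(0.03, 0.12)),
            "distribution": float(rng.uniform(0.02, 0.06)),
            "consumption": float(rng.uniform(0.08, 0.22)),
        }
        for f in foods
    }

    # technical conversion factors
    tcf = {}
    for cid, crop in crops.items():
        if not crop.is_food_crop:
            continue
        agro = _GROUP_AGRO[crop.food_group]
        entry = {"main_fraction": agro["main"], "byproducts": {}}
        if agro["bp"] is not None:
            entry["byproducts"] = {agro["bp"][0]: agro["bp"][1]}
        tcf[cid] = entry

    residual = ResidualParams(stage_waste_fracs=stage_fracs, tcf=tcf)

    inst = FoodSystemInstance(
        name=f"synthetic_z{n_zones}_k{n_countries}_c{n_crops}"
             f"_a{n_animal_systems}_s{seed}",
        zones={}, crops=crops, animal_systems=systems,
        feed_items=feed_items, fish_stocks=fish_stocks,
        nutrient_specs={}, food_group_bounds=_standard_group_bounds(),
        residual_params=residual, emission_constants=EmissionConstants(),
        population_by_country=population, country_coordinates=coords,
        grass_feed_map={"temporary_grassland": "grass_temporary",
                        "permanent_pasture": "grass_permanent",
                        "rangeland": "grass_rangeland"},
    )

    # ---- "current" baseline construction -----------------------------------
    _build_current_state(inst, zone_ids, zone_country, zone_weight,
                         zone_climate, zone_soil)
    _build_nutrient_specs(inst)

    # waste-pool nutrient content: supply-weighted mean over current foods
    n_tot = p_tot = m_tot = 0.0
    for f in inst.food_ids():
        g = inst.food_group_of(f)
        m = _CURRENT_SUPPLY_G_DAY.get(g, 0.0)
        n, p = inst.food_np_conc(f)
        n_tot += m * n
        p_tot += m * p
        m_tot += m
    if m_tot > 0:
        inst.residual_params.waste_n_conc_kg_t = n_tot / m_tot
        inst.residual_params.waste_p_conc_kg_t = p_tot / m_tot

    problems = validate_instance(inst)
    if problems:
        raise GenerationError(
            "generated instance fails validation: " + "; ".join(
                str(p) for p in problems[:5]))
    _structural_checks(inst)
    return inst


def _standard_group_bounds() -> dict[str, FoodGroupBound]:
    bounds = {
        g: FoodGroupBound(g, mn, mx)
        for g, (mn, mx) in EAT_LANCET_BOUNDS_G_DAY.items()
    }
    bounds["grains"] = FoodGroupBound(
        "grains", 0.0, None, max_energy_share=GRAINS_MAX_ENERGY_SHARE)
    # oil_fat and "other" carry no guardrail
    return bounds


def _chain_keep(inst: FoodSystemInstance, food: str,
                stages: tuple[str, ...]) -> float:
    fr = inst.residual_params.stage_fracs_for(food)
    keep = 1.0
    for st in stages:
        keep *= 1.0 - fr.get(st, 0.0)
    return keep


def _foods_by_group(inst: FoodSystemInstance) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for f in inst.food_ids():
        out.setdefault(inst.food_group_of(f), []).append(f)
    return out


#: baseline ration recipes: energy fractions per feed item
_RATION_RECIPES: dict[str, dict[str, float]] = {
    "dairy": {"grass_permanent": 0.45, "grass_temporary": 0.20,
              "fodder_clover_feed": 0.20, "fodder_maize_feed": 0.15},
    "beef": {"grass_permanent": 0.50, "grass_temporary": 0.20,
             "fodder_clover_feed": 0.15, "fodder_maize_feed": 0.15},
    "pig": {"grain_feed": 0.50, "fodder_maize_feed": 0.15,
            "fodder_legume_feed": 0.35},
    "broiler": {"grain_feed": 0.45, "fodder_legume_feed": 0.55},
    "layer": {"grain_feed": 0.45, "fodder_legume_feed": 0.55},
    "salmon": {"fish_meal": 0.45, "fodder_legume_feed": 0.35,
               "grain_feed": 0.20},
    "tilapia": {"fish_meal": 0.35, "fodder_legume_feed": 0.35,
                "grain_feed": 0.30},
}


def _build_current_state(inst: FoodSystemInstance, zone_ids, zone_country,
                         zone_weight, zone_climate, zone_soil) -> None:
    """Construct current diet, areas, fodder, grass and fertilizer so the
    fixed-area calibration scenario is feasible by construction."""
    by_group = _foods_by_group(inst)
    countries = sorted(inst.population_by_country)

    # current supply split equally over the group's foods
    current_supply: dict[str, dict[str, float]] = {}
    food_supply: dict[tuple[str, str], float] = {}  # (food, country) g/day
    for k in countries:
        current_supply[k] = {}
        for g, total in _CURRENT_SUPPLY_G_DAY.items():
            members = by_group.get(g, [])
            if not members:
                continue
            per = total / len(members)
            prot = 0.0
            for f in members:
                food_supply[(f, k)] = per
                prot += per * inst.food_composition_of(f).get("protein", 0.0)
            current_supply[k][g] = prot
    inst.current_supply_protein = current_supply

    # crop mass needed per (crop, country): food chain + feed for animals
    crop_need: dict[tuple[str, str], float] = {}
    feed_need: dict[tuple[str, str], float] = {}    # (feed item, country) t
    grass_need: dict[tuple[str, str], float] = {}   # (grass type, country) t
    for k in countries:
        pop = inst.population_by_country[k]
        for f in inst.food_ids():
            supply = food_supply.get((f, k), 0.0)
            if supply <= 0:
                continue
            dlv_t = supply * pop * _DAYS / 1e6
            if f in inst.crops:
                keep = _chain_keep(inst, f,
                                   ("post_harvest", "processing", "distribution"))
                main = float(inst.residual_params.tcf
                             .get(f, {}).get("main_fraction", 1.0))
                crop_need[(f, k)] = crop_need.get((f, k), 0.0) \
                    + dlv_t / (keep * main)
            elif f != "wild_fish":
                sid = f[: -len("_product")]
                system = inst.animal_systems[sid]
                keep = _chain_keep(inst, f,
                                   ("post_harvest", "processing", "distribution"))
                product_t = dlv_t / keep
                units = product_t / system.output_t_per_unit
                aux = system.parent_stock_ratio + system.repro_stock_ratio
                energy = units * (
                    system.output_t_per_unit
                    * system.requirement_per_t_product["energy_mj_per_t"]
                    + aux * system.aux_requirement_per_unit["energy_mj_per_t"])
                recipe = _RATION_RECIPES[system.species]
                for fid, frac in recipe.items():
                    item = inst.feed_items[fid]
                    e_per_t = item.comp_for(system.species)["energy_mj_per_t"]
                    t_needed = energy * frac / e_per_t
                    if item.origin == "grass":
                        gtype = {"grass_temporary": "temporary_grassland",
                                 "grass_permanent": "permanent_pasture",
                                 "grass_rangeland": "rangeland"}[fid]
                        grass_need[(gtype, k)] = grass_need.get(
                            (gtype, k), 0.0) + t_needed
                    elif item.origin == "fodder_crop":
                        feed_need[(fid, k)] = feed_need.get(
                            (fid, k), 0.0) + t_needed
                    # by-product/fish-meal shares come from existing streams

    # convert whole-crop feed needs to crop mass (with headroom)
    feed_crop_of = {c.feed_value_id: cid for cid, c in inst.crops.items()
                    if c.feed_value_id}
    for (fid, k), t in feed_need.items():
        cid = feed_crop_of[fid]
        crop_need[(cid, k)] = crop_need.get((cid, k), 0.0) + 1.25 * t

    # allocate areas across the country's zones, proportional to zone weight
    current_areas: dict[str, dict[str, float]] = {}
    zone_area_total: dict[str, float] = {z: 0.0 for z in zone_ids}
    for (cid, k), mass in sorted(crop_need.items()):
        crop = inst.crops[cid]
        zs = [z for z in zone_ids if zone_country[z] == k]
        weights = np.array([zone_weight[z] for z in zs])
        weights = weights / weights.sum()
        for z, w in zip(zs, weights):
            area = mass * w / crop.yield_by_zone[z]
            current_areas.setdefault(cid, {})[z] = \
                current_areas.get(cid, {}).get(z, 0.0) + area
            zone_area_total[z] += area
    inst.current_areas = current_areas

    # zone land endowments: cropland 2.5x current cultivation; grassland
    # sized from baseline grazing needs with headroom
    for z in zone_ids:
        k = zone_country[z]
        zs = [zz for zz in zone_ids if zone_country[zz] == k]
        wsum = sum(zone_weight[zz] for zz in zs)
        share = zone_weight[z] / wsum
        cropland = max(2.5 * zone_area_total[z],
                       0.05 * inst.population_by_country[k])
        areas = {"cropland": cropland}
        for gtype, fid in (("temporary_grassland", "grass_temporary"),
                           ("permanent_pasture", "grass_permanent"),
                           ("rangeland", "grass_rangeland")):
            need_t = grass_need.get((gtype, k), 0.0) * share
            gy = {"grass_temporary": 10.0, "grass_permanent": 8.0,
                  "grass_rangeland": 4.0}[fid]
            base_ha = {"temporary_grassland": 0.02, "permanent_pasture": 0.08,
                       "rangeland": 0.05}[gtype] * inst.population_by_country[k] * share
            areas[gtype] = max(1.6 * need_t / gy, base_ha)
            inst.grass_yield.setdefault(z, {})[gtype] = gy
        inst.zones[z] = Zone(
            zone_id=z, country_id=k, area_by_land_type=areas,
            climate_class=zone_climate[z], soil_class=zone_soil[z],
            coordinates=(inst.country_coordinates[k][0]
                         + 50.0 * zone_ids.index(z), 0.0))

    # artificial fertilizer: 1.3x the removal-based requirement of current areas
    total_req_t = 0.0
    for cid, zmap in current_areas.items():
        crop = inst.crops[cid]
        for z, a in zmap.items():
            y = crop.yield_by_zone[z]
            rrr = crop.residue_to_product_ratio
            n_rem = a * y * (crop.n_conc_product + rrr * crop.n_conc_residue)
            p_rem = a * y * (crop.p_conc_product + rrr * crop.p_conc_residue)
            total_req_t += (n_rem * 1.35 + p_rem * 1.125) / 1000.0
    inst.current_artificial_fertilizer_t = 1.3 * total_req_t
    inst.current_sludge_t = {k: 0.017 * inst.population_by_country[k]
                             for k in countries}


def _build_nutrient_specs(inst: FoodSystemInstance) -> None:
    """Anchor per-nutrient bounds to the reference healthy intake."""
    by_group = _foods_by_group(inst)
    ref = {n: 0.0 for n in NUTRIENTS}
    for g, total in _REFERENCE_INTAKE_G_DAY.items():
        members = by_group.get(g, [])
        if not members:
            continue
        per = total / len(members)
        for f in members:
            comp = inst.food_composition_of(f)
            for n in NUTRIENTS:
                ref[n] += per * comp.get(n, 0.0)
    specs: dict[str, NutrientSpec] = {}
    for n in NUTRIENTS:
        lo = _MIN_FACTORS.get(n)
        hi = _MAX_FACTORS.get(n)
        mn = ref[n] * lo if (lo and ref[n] > 0) else None
        mx = ref[n] * hi if (hi and ref[n] > 0) else None
        specs[n] = NutrientSpec(n, NUTRIENT_UNITS[n], mn, mx)
    inst.nutrient_specs = specs


def _structural_checks(inst: FoodSystemInstance) -> None:
    """Assert the structural-realism requirements of generated instances."""
    for f in inst.food_ids():
        fr = inst.residual_params.stage_fracs_for(f)
        if not (0.0 < fr.get("consumption", 0.0) < 0.3):
            raise GenerationError(
                f"consumption waste fraction for {f} outside (0, 0.3)")
    for fid, item in inst.feed_items.items():
        if item.origin == "grass":
            for sp in _SPECIES_ORDER:
                if sp not in RUMINANT_SPECIES and item.legal_for(sp):
                    raise GenerationError(
                        f"grass feed {fid} legal for non-ruminant {sp}")
    for cid, entry in inst.residual_params.tcf.items():
        total = entry["main_fraction"] + sum(entry["byproducts"].values())
        if total > 1.0 + 1e-9:
            raise GenerationError(f"TCF fractions for {cid} sum above 1")
    for f in inst.food_ids():
        if inst.food_group_of(f) in ("dairy", "red_meat", "chicken", "eggs",
                                     "fish"):
            if inst.food_composition_of(f).get("vitamin_b12", 0.0) <= 0:
                raise GenerationError(f"animal food {f} lacks vitamin B12")
        elif inst.food_composition_of(f).get("vitamin_b12", 0.0) != 0:
            raise GenerationError(f"plant food {f} carries vitamin B12")


# ---------------------------------------------------------------------------
# population scaling, known-optimum and oracle instances
# ---------------------------------------------------------------------------

def scale_population(inst: FoodSystemInstance, factor: float
                     ) -> FoodSystemInstance:
    """Return a copy with only the population fields scaled by ``factor``."""
    if factor <= 0:
        raise ValueError("population scale factor must be > 0")
    out = copy.deepcopy(inst)
    out.population_by_country = {
        k: v * factor for k, v in inst.population_by_country.items()}
    return out


@dataclass(frozen=True)
class KnownOptimum:
    objective_ha: float
    areas: dict[tuple[str, str], float]
    diet_g_day: float
    binding_nutrient: str


def generate_known_optimum_instance(seed: int = 7
                                    ) -> tuple[FoodSystemInstance, KnownOptimum]:
    """A tiny instance whose land-minimizing optimum is known in closed form.

    One crop strictly dominates the alternative in every constrained
    nutrient per hectare (identical composition, double yield), so the
    optimal diet uses the dominant crop alone and the optimum follows from
    the binding nutrient minimum. All waste fractions are zero, processing
    keeps the full mass, and no fertilizer is required, so

        area* = intake* x population x 365 / 1e6 / yield,

    with intake* = max over bounded nutrients of (minimum / concentration).
    """
    rng = np.random.default_rng(seed)
    pop = 1e6
    yield_a = float(rng.uniform(6.0, 10.0))
    yield_b = yield_a / 2.0
    energy_conc = float(rng.uniform(1.8, 2.4))    # kcal / g
    protein_conc = float(rng.uniform(0.06, 0.10))
    energy_min = float(rng.uniform(2000.0, 2400.0))
    protein_min = float(rng.uniform(50.0, 70.0))

    comp = {n: 0.0 for n in NUTRIENTS}
    comp.update(fresh_weight=1.0, energy=energy_conc, protein=protein_conc,
                carbohydrates=0.5, fibre=0.03)

    def crop(cid: str, y: float) -> Crop:
        return Crop(crop_id=cid, food_group="other",
                    yield_by_zone={"Z1": y}, rotation_max_frequency=1.0,
                    food_composition=dict(comp))

    intake = max(energy_min / energy_conc, protein_min / protein_conc)
    binding = ("energy" if energy_min / energy_conc >= protein_min / protein_conc
               else "protein")
    area = intake * pop * _DAYS / 1e6 / yield_a

    specs = {n: NutrientSpec(n, NUTRIENT_UNITS[n]) for n in NUTRIENTS}
    specs["energy"] = NutrientSpec("energy", "kcal", energy_min, None)
    specs["protein"] = NutrientSpec("protein", "g", protein_min, None)

    inst = FoodSystemInstance(
        name=f"known_optimum_s{seed}",
        zones={"Z1": Zone("Z1", "C1",
                          {"cropland": 50.0 * area, "temporary_grassland": 0.0,
                           "permanent_pasture": 0.0, "rangeland": 0.0},
                          "temperate_wet", "other", (0.0, 0.0))},
        crops={"dominant": crop("dominant", yield_a),
               "dominated": crop("dominated", yield_b)},
        animal_systems={}, feed_items={}, fish_stocks={},
        nutrient_specs=specs,
        food_group_bounds={},
        residual_params=ResidualParams(stage_waste_fracs={}, tcf={}),
        emission_constants=EmissionConstants(),
        population_by_country={"C1": pop},
        country_coordinates={"C1": (0.0, 0.0)},
    )
    expected = KnownOptimum(
        objective_ha=area,
        areas={("dominant", "Z1"): area},
        diet_g_day=intake,
        binding_nutrient=binding,
    )
    return inst, expected


def generate_tiny_instance(seed: int, n_crops: int = 2
                           ) -> FoodSystemInstance:
    """Random crop-only single-zone instance for oracle cross-checks.

    Small enough for exhaustive grid search: one country, one zone, two or
    three food crops with random yields, compositions and waste chains, and
    nutrient minima on energy and protein only. Feasible by construction
    (any single crop can satisfy the minima within the land endowment).
    """
    if not (1 <= n_crops <= 3):
        raise ValueError("tiny instances support 1-3 crops")
    rng = np.random.default_rng(seed)
    pop = 1e6
    crops: dict[str, Crop] = {}
    stage_fracs = {}
    tcf = {}
    for i in range(n_crops):
        cid = f"crop{i + 1}"
        comp = {n: 0.0 for n in NUTRIENTS}
        comp.update(
            fresh_weight=1.0,
            energy=float(rng.uniform(1.5, 3.0)),
            protein=float(rng.uniform(0.05, 0.15)),
            fibre=float(rng.uniform(0.01, 0.1)),
            carbohydrates=float(rng.uniform(0.2, 0.7)),
        )
        crops[cid] = Crop(
            crop_id=cid, food_group="other",
            yield_by_zone={"Z1": float(rng.uniform(3.0, 10.0))},
            rotation_max_frequency=1.0,
            food_composition=comp,
        )
        stage_fracs[cid] = {
            "post_harvest": float(rng.uniform(0.0, 0.08)),
            "processing": float(rng.uniform(0.0, 0.1)),
            "distribution": float(rng.uniform(0.0, 0.05)),
            "consumption": float(rng.uniform(0.05, 0.15)),
        }
        tcf[cid] = {"main_fraction": float(rng.uniform(0.7, 1.0)),
                    "byproducts": {}}

    specs = {n: NutrientSpec(n, NUTRIENT_UNITS[n]) for n in NUTRIENTS}
    specs["energy"] = NutrientSpec("energy", "kcal",
                                   float(rng.uniform(1800.0, 2400.0)), None)
    specs["protein"] = NutrientSpec("protein", "g",
                                    float(rng.uniform(40.0, 70.0)), None)

    return FoodSystemInstance(
        name=f"tiny_s{seed}",
        zones={"Z1": Zone("Z1", "C1",
                          {"cropland": 5e6, "temporary_grassland": 0.0,
                           "permanent_pasture": 0.0, "rangeland": 0.0},
                          "temperate_wet", "other", (0.0, 0.0))},
        crops=crops, animal_systems={}, feed_items={}, fish_stocks={},
        nutrient_specs=specs, food_group_bounds={},
        residual_params=ResidualParams(stage_waste_fracs=stage_fracs, tcf=tcf),
        emission_constants=EmissionConstants(),
        population_by_country={"C1": pop},
        country_coordinates={"C1": (0.0, 0.0)},
    )
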