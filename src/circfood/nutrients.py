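"""Nutrient and food-group vocabularies.

The model tracks 42 human-nutrition values per food (fresh weight, energy,
macronutrients, fat types, minerals, vitamins and essential amino acids) and
14 food groups. Food-group intake guardrails follow the EAT-Lancet reference
ranges; the grains bound is expressed as a maximum share of energy intake
rather than grams per day.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# The 42 tracked nutrients, with the unit each is expressed in per capita per
# day (composition tables carry the same unit per gram of fresh food).
# ---------------------------------------------------------------------------
NUTRIENT_UNITS: dict[str, str] = {
    # general
    "fresh_weight": "g",
    "energy": "kcal",
    # macronutrients
    "protein": "g",
    "fat_total": "g",
    "carbohydrates": "g",
    "fibre": "g",
    # fat types
    "saturated_fat": "g",
    "linoleic_acid": "g",
    "alpha_linolenic_acid": "g",
    "dha": "mg",
    "epa": "mg",
    "cholesterol": "mg",
    # minerals
    "sodium": "mg",
    "potassium": "mg",
    "calcium": "mg",
    "phosphorus": "mg",
    "magnesium": "mg",
    "iron": "mg",
    "copper": "mg",
    "selenium": "ug",
    "zinc": "mg",
    "iodine": "ug",
    # vitamins
    "vitamin_a": "ug",
    "vitamin_b1": "mg",
    "vitamin_b2": "mg",
    "vitamin_b3": "mg",
    "vitamin_b6": "mg",
    "vitamin_b9": "ug",
    "vitamin_b12": "ug",
    "vitamin_c": "mg",
    "vitamin_d": "ug",
    "vitamin_e": "mg",
    "vitamin_k": "ug",
    # essential amino acids
    "histidine": "g",
    "isoleucine": "g",
    "leucine": "g",
    "lysine": "g",
    "methionine": "g",
    "phenylalanine": "g",
    "threonine": "g",
    "tryptophan": "g",
    "valine": "g",
}

NUTRIENTS: tuple[str, ...] = tuple(NUTRIENT_UNITS)
assert len(NUTRIENTS) == 42

#: Nutrients found only in animal-source foods.
ANIMAL_ONLY_NUTRIENTS: tuple[str, ...] = ("vitamin_b12", "cholesterol", "dha", "epa")

# ---------------------------------------------------------------------------
# Food groups. "fodder" marks feed-only crops and never appears in diets.
# ---------------------------------------------------------------------------
FOOD_GROUPS: tuple[str, ...] = (
    "grains",
    "tubers",
    "vegetables",
    "fruit",
    "dairy",
    "red_meat",
    "chicken",
    "eggs",
    "fish",
    "legumes",
    "nuts_seeds",
    "oil_fat",
    "sugar",
    "other",
)

FODDER_GROUP = "fodder"

ANIMAL_GROUPS: tuple[str, ...] = ("dairy", "red_meat", "chicken", "eggs", "fish")

#: EAT-Lancet style intake guardrails in g fresh / capita / day
#: (min, max); grains carry a max share of energy intake instead.
EAT_LANCET_BOUNDS_G_DAY: dict[str, tuple[float, float]] = {
    "tubers": (0.0, 100.0),
    "vegetables": (200.0, 600.0),
    "fruit": (100.0, 300.0),
    "dairy": (0.0, 500.0),
    "red_meat": (0.0, 28.0),
    "chicken": (0.0, 58.0),
    "eggs": (0.0, 25.0),
    "fish": (0.0, 100.0),
    "legumes": (0.0, 225.0),
    "nuts_seeds": (0.0, 75.0),
    "sugar": (0.0, 31.0),
}

#: Maximum share of dietary energy supplied by the grains group.
GRAINS_MAX_ENERGY_SHARE = 0.60

#: Map animal species to the food group of their product.
SPECIES_FOOD_GROUP: dict[str, str] = {
    "dairy": "dairy",
    "beef": "red_meat",
    "pig": "red_meat",
    "broiler": "chicken",
    "layer": "eggs",
    "salmon": "fish",
    "tilapia": "fish",
}

RUMINANT_SPECIES: tuple[str, ...] = ("dairy", "beef")
FISH_SPECIES: tuple[str, ...] = ("salmon", "tilapia")
MONOGASTRIC_SPECIES: tuple[str, ...] = ("pig", "broiler", "layer")

WASTE_STAGES: tuple[str, ...] = (
    "post_harvest",
    "processing",
    "distribution",
    "consumption",
)
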