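"""Per-capita nutrition accounting and dietary constraint checks.

Three dietary constraint families are evaluated here, mirroring the three
ways scenarios restrict consumption: (1) matching current protein supply per
food group and country; (2) per-nutrient minimum/maximum intakes (EFSA-style
dietary reference values, supplied as instance data); and (3) food-group
intake guardrails (EAT-Lancet style), where the grains bound is a maximum
share of energy intake.

All bounds are inclusive (closed half-spaces, matching LP feasibility).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .nutrients import NUTRIENTS, WASTE_STAGES


Diet = Mapping[str, float]  # food -> g fresh / capita / day


def zero_nutrient_vector() -> dict[str, float]:
    return {n: 0.0 for n in NUTRIENTS}


def diet_nutrients(diet: Diet,
                   composition: Mapping[str, Mapping[str, float]]) -> dict[str, float]:
    """Nutrient intake vector of a diet (linear in the diet quantities).

    ``composition[food][nutrient]`` is the amount per gram fresh food; the
    result is per capita per day in each nutrient's own unit.
    """
    out = zero_nutrient_vector()
    for food, grams in diet.items():
        if food not in composition:
            raise KeyError(f"no composition row for food {food!r}")
        if grams < 0:
            raise ValueError(f"negative diet amount for {food!r}")
        row = composition[food]
        for n in NUTRIENTS:
            out[n] += grams * row.get(n, 0.0)
    return out


def apply_waste_chain(
    supply: Diet,
    stage_waste_fracs: Mapping[str, Mapping[str, float]],
) -> tuple[dict[str, float], dict[str, dict[str, float]]]:
    """Reduce a supply profile to intake through the stage-wise waste chain.

    ``intake = supply * prod_over_stages (1 - frac)``; the amount lost at
    each stage is returned separately so that consumption waste can be routed
    to feed or compost. Mass is conserved exactly:
    ``intake + sum of stage losses == supply`` per food.
    """
    intake: dict[str, float] = {}
    losses: dict[str, dict[str, float]] = {}
    for food, amount in supply.items():
        fracs = stage_waste_fracs.get(food, {})
        remaining = float(amount)
        per_stage: dict[str, float] = {}
        for stage in WASTE_STAGES:
            frac = float(fracs.get(stage, 0.0))
            if not (0.0 <= frac < 1.0):
                raise ValueError(
                    f"waste fraction for {food!r} at {stage!r} must be in [0, 1)")
            lost = remaining * frac
            per_stage[stage] = lost
            remaining -= lost
        intake[food] = remaining
        losses[food] = per_stage
    return intake, losses


@dataclass(frozen=True)
class BoundViolation:
    nutrient: str
    bound: str      # "min" or "max"
    limit: float
    value: float

    def __str__(self) -> str:  # pragma: no cover
        rel = "<" if self.bound == "min" else ">"
        return f"{self.nutrient}: {self.value:.4g} {rel} {self.bound} {self.limit:.4g}"


def nutrient_bound_violations(
    intake: Mapping[str, float],
    specs: Mapping[str, "object"],
) -> list[BoundViolation]:
    """Empty iff min <= intake <= max for every bounded nutrient (inclusive)."""
    out: list[BoundViolation] = []
    for nid in sorted(specs):
        spec = specs[nid]
        value = float(intake.get(nid, 0.0))
        lo = spec.min_per_capita_day
        hi = spec.max_per_capita_day
        if lo is not None and value < lo - 1e-9 * max(1.0, abs(lo)):
            out.append(BoundViolation(nid, "min", float(lo), value))
        if hi is not None and value > hi + 1e-9 * max(1.0, abs(hi)):
            out.append(BoundViolation(nid, "max", float(hi), value))
    return out


@dataclass(frozen=True)
class GroupViolation:
    group: str
    bound: str
    limit: float
    value: float


def food_group_violations(
    intake_diet: Diet,
    group_of: Mapping[str, str],
    bounds: Mapping[str, "object"],
    energy_by_food: Mapping[str, float],
) -> list[GroupViolation]:
    """Check food-group intake guardrails on an intake diet.

    Grams-per-day groups are checked directly; the grains group is checked as
    a share of total energy intake. ``energy_by_food`` maps each food to its
    energy content per gram fresh.
    """
    totals: dict[str, float] = {}
    energy_totals: dict[str, float] = {}
    total_energy = 0.0
    for food, grams in intake_diet.items():
        if food not in group_of:
            raise KeyError(f"food {food!r} not mapped to a food group")
        g = group_of[food]
        totals[g] = totals.get(g, 0.0) + grams
        e = grams * float(energy_by_food.get(food, 0.0))
        energy_totals[g] = energy_totals.get(g, 0.0) + e
        total_energy += e

    out: list[GroupViolation] = []
    for gid in sorted(bounds):
        b = bounds[gid]
        value = totals.get(gid, 0.0)
        if b.max_energy_share is not None:
            if total_energy > 0:
                share = energy_totals.get(gid, 0.0) / total_energy
                if share > b.max_energy_share + 1e-9:
                    out.append(GroupViolation(gid, "max_energy_share",
                                              b.max_energy_share, share))
            continue
        if value < b.min_g_day - 1e-9:
            out.append(GroupViolation(gid, "min", b.min_g_day, value))
        if b.max_g_day is not None and value > b.max_g_day + 1e-9:
            out.append(GroupViolation(gid, "max", b.max_g_day, value))
    return out


@dataclass(frozen=True)
class ProteinShortfall:
    country: str
    group: str
    required_g_day: float
    delivered_g_day: float

    @property
    def shortfall_g_day(self) -> float:
        return self.required_g_day - self.delivered_g_day


def protein_supply_match(
    delivered_protein: Mapping[str, Mapping[str, float]],
    current_supply: Mapping[str, Mapping[str, float]],
) -> list[ProteinShortfall]:
    """Shortfalls where delivered protein < current supply per (country, group).

    Matching is a minimum (>=), not an equality: scenarios may over-deliver
    protein in a group without penalty. Both arguments are
    ``country -> food group -> g protein / capita / day``.
    """
    out: list[ProteinShortfall] = []
    for country in sorted(current_supply):
        for group in sorted(current_supply[country]):
            req = float(current_supply[country][group])
            got = float(delivered_protein.get(country, {}).get(group, 0.0))
            if got < req - 1e-9 * max(1.0, req):
                out.append(ProteinShortfall(country, group, req, got))
    return out
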