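"""Crop suitability, rotation shares, and N/P fertilizer balance.

Crop rotations are represented statically: a crop grown at most once every k
years may occupy at most 1/k of a zone's cropland in the yearly average.
Fertilizer requirements follow a nutrient-removal logic: the N and P exported
in the harvested product and the aboveground residues must be returned, plus
unavoidable losses (a fixed 12.5% for P; volatilization and leaching/run-off
fractions for N that depend on the fertilizer source and the zone's climate
moisture). Crop residues stay on the field; their nutrients are nevertheless
part of the removal-based requirement (no offset by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .instance import Crop, EmissionConstants, FoodSystemInstance, Zone


def rotation_share(rotation_max_frequency: float) -> float:
    """Maximum annual area share implied by a 1-in-k rotation frequency.

    Accepts either the frequency as a fraction (e.g. 1/6) or the integer k;
    a 1:4 rotation with four crops gives 0.25 ha per ha cropland per year.
    """
    f = float(rotation_max_frequency)
    if f > 1.0:          # interpret as k years
        if f < 1.0 or f != int(f):
            raise ValueError("rotation interval k must be an integer >= 1")
        f = 1.0 / f
    if not (0.0 < f <= 1.0):
        raise ValueError("rotation frequency must be in (0, 1]")
    return f


def suitable_crops(zone: Zone, inst: FoodSystemInstance) -> dict[str, float]:
    """Crops growable in a zone with their binding annual area cap (ha).

    A crop with no yield entry in the zone is unsuitable. The cap is the
    minimum of the rotation-share cap (share x zone cropland) and, where
    declared (rice and minor crops), the current-acreage cap.
    """
    cropland = zone.cropland_ha()
    out: dict[str, float] = {}
    for cid, crop in sorted(inst.crops.items()):
        if zone.zone_id not in crop.yield_by_zone:
            continue
        cap = rotation_share(crop.rotation_max_frequency) * cropland
        if crop.acreage_cap_by_zone and zone.zone_id in crop.acreage_cap_by_zone:
            cap = min(cap, float(crop.acreage_cap_by_zone[zone.zone_id]))
        out[cid] = cap
    return out


def crop_nutrient_removal(crop: Crop, zone_id: str, area_ha: float
                          ) -> dict[str, float]:
    """N and P (kg) removed in harvest plus aboveground residues.

    removal = area x yield x (conc_product + residue_ratio x conc_residue),
    linear in area.
    """
    if zone_id not in crop.yield_by_zone:
        raise ValueError(f"crop {crop.crop_id!r} is unsuitable in zone {zone_id!r}")
    if area_ha < 0:
        raise ValueError("area must be >= 0")
    y = crop.yield_by_zone[zone_id]
    mass = area_ha * y
    rrr = crop.residue_to_product_ratio
    return {
        "N": mass * (crop.n_conc_product + rrr * crop.n_conc_residue),
        "P": mass * (crop.p_conc_product + rrr * crop.p_conc_residue),
    }


def n_loss_fracs(source: str, zone: Zone, ec: EmissionConstants
                 ) -> tuple[float, float]:
    """(volatilization fraction, leaching fraction) for N from ``source``."""
    moist = "wet" if zone.is_wet else "dry"
    ef = ec.soil_ef(source, moist)
    return float(ef["frac_volat"]), float(ef["frac_leach"])


def fertilizer_requirement(
    crop: Crop,
    zone: Zone,
    area_ha: float,
    ec: EmissionConstants,
    n_source: str = "artificial",
    loss_mode: str = "multiplicative",
    residues_offset: bool = False,
) -> dict[str, float]:
    """Removal-based N and P requirement (kg) for an area of a crop.

    P requirement multiplies removal by (1 + unavoidable loss 12.5%); the N
    requirement adds the volatilization and leaching/run-off fractions of the
    (default artificial) fertilizer source in the zone's climate. N_req is
    always >= N removal.

    ``loss_mode="divisor"`` switches to the alternative reading in which the
    loss fraction scales the requirement as removal / (1 - loss).
    ``residues_offset=True`` credits the nutrients in residues left on the
    field against the requirement (off by default: the requirement covers
    harvest plus aboveground residues).
    """
    if loss_mode not in ("multiplicative", "divisor"):
        raise ValueError(f"unknown loss mode {loss_mode!r}")
    removal = crop_nutrient_removal(crop, zone.zone_id, area_ha)
    if residues_offset:
        y = crop.yield_by_zone[zone.zone_id]
        rrr = crop.residue_to_product_ratio
        removal["N"] -= area_ha * y * rrr * crop.n_conc_residue
        removal["P"] -= area_ha * y * rrr * crop.p_conc_residue
    volat, leach = n_loss_fracs(n_source, zone, ec)
    if loss_mode == "multiplicative":
        n_factor = 1.0 + volat + leach
        p_factor = 1.0 + ec.p_unavoidable_loss
    else:
        n_factor = 1.0 / (1.0 - min(volat + leach, 0.99))
        p_factor = 1.0 / (1.0 - ec.p_unavoidable_loss)
    return {"N": removal["N"] * n_factor, "P": removal["P"] * p_factor}


def delivered_n_fraction(source: str, zone: Zone, ec: EmissionConstants) -> float:
    """Fraction of applied N from ``source`` that counts toward the removal.

    With requirement = removal x (1 + losses), one kg applied covers
    1 / (1 + losses) kg of removal; expressing the balance this way keeps it
    well defined when several sources with different loss fractions are mixed.
    """
    volat, leach = n_loss_fracs(source, zone, ec)
    return 1.0 / (1.0 + volat + leach)


@dataclass(frozen=True)
class FertilizerDeficit:
    crop: str
    zone: str
    nutrient: str
    required_kg: float
    supplied_kg: float

    @property
    def deficit_kg(self) -> float:
        return self.required_kg - self.supplied_kg


def fertilizer_supply_balance(
    applications: Mapping[tuple[str, str, str], tuple[float, float]],
    requirements: Mapping[tuple[str, str], dict[str, float]],
    organic_np_ratio: Mapping[str, float],
) -> list[FertilizerDeficit]:
    """Check per-(crop, zone) N and P coverage of removal-based requirements.

    ``applications`` maps (source, crop, zone) to (kg N, kg P) applied; for
    the four organic sources the P entry is ignored and recomputed from the
    source's fixed N:P ratio (organic fertilizers deliver N and P jointly).
    Organic nutrients are fully plant-available. Returns the list of
    deficits; empty iff supply >= requirement everywhere.
    """
    supplied: dict[tuple[str, str], dict[str, float]] = {}
    for (source, crop, zone), (n_kg, p_kg) in applications.items():
        if n_kg < 0 or p_kg < 0:
            raise ValueError("negative fertilizer application")
        if source in organic_np_ratio:
            p_kg = n_kg / float(organic_np_ratio[source])
        acc = supplied.setdefault((crop, zone), {"N": 0.0, "P": 0.0})
        acc["N"] += n_kg
        acc["P"] += p_kg

    out: list[FertilizerDeficit] = []
    for (crop, zone) in sorted(requirements):
        req = requirements[(crop, zone)]
        got = supplied.get((crop, zone), {"N": 0.0, "P": 0.0})
        for nut in ("N", "P"):
            need = float(req.get(nut, 0.0))
            have = float(got[nut])
            if have < need - 1e-9 * max(1.0, need):
                out.append(FertilizerDeficit(crop, zone, nut, need, have))
    return out
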