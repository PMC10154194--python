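"""Greenhouse-gas inventory: CH4, N2O and CO2 by source, aggregated to CO2e.

Emission formulas follow IPCC-style tier-2 livestock accounting and tier-1
soil accounting:

* enteric CH4 = gross energy intake x Ym / 55.65 (MJ per kg CH4)
* manure-management CH4 = VS x MCF x B0 x 0.67 (m3 -> kg CH4)
* manure/soil N2O: applied or excreted N x emission factor, direct plus
  indirect (volatilized and leached N), converted N -> N2O by 44/28
* aquaculture N2O: 1.8% of unconsumed-plus-excreted N
* compost: N2O from composted N; CH4 from compost carbon via a C:N ratio of 15
* transport CO2: ton-kilometres x emission factor

Gases aggregate with 100-yr GWPs of 28 (biogenic CH4) and 265 (N2O). CH4
from rice and CO2 from soils and cropping are excluded by design. Emissions
are computed post hoc from a solved scenario; only the per-capita transport
cap acts as a hard constraint inside the optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .instance import EmissionConstants

GASES: tuple[str, ...] = ("CH4", "N2O", "CO2")
CATEGORIES: tuple[str, ...] = (
    "enteric",
    "manure_mgmt_CH4",
    "manure_N2O",
    "grassland_N2O",
    "aquaculture_N2O",
    "soil_N2O",
    "organic_soil_N2O",
    "fertilizer_production",
    "compost",
    "transport",
)

N_TO_N2O = 44.0 / 28.0


@dataclass
class GHGInventory:
    """Emissions by (source category, gas) in kg/yr, plus CO2e totals."""

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    gwp_ch4: float = 28.0
    gwp_n2o: float = 265.0

    def add(self, category: str, gas: str, kg: float) -> None:
        if category not in CATEGORIES:
            raise KeyError(f"unknown source category {category!r}")
        if gas not in GASES:
            raise KeyError(f"unknown gas {gas!r}")
        if kg < -1e-9:
            raise ValueError("emissions must be >= 0")
        key = (category, gas)
        self.entries[key] = self.entries.get(key, 0.0) + max(0.0, kg)

    def by_gas(self, gas: str) -> float:
        return sum(v for (c, g), v in self.entries.items() if g == gas)

    def by_category_co2e(self, category: str) -> float:
        total = 0.0
        for (c, g), v in self.entries.items():
            if c != category:
                continue
            total += v * {"CH4": self.gwp_ch4, "N2O": self.gwp_n2o, "CO2": 1.0}[g]
        return total

    def total_co2e(self) -> float:
        return (self.by_gas("CO2")
                + self.gwp_ch4 * self.by_gas("CH4")
                + self.gwp_n2o * self.by_gas("N2O"))


def enteric_ch4(gross_energy_mj: float, ym_percent: float,
                ec: EmissionConstants | None = None) -> float:
    """Enteric fermentation CH4 (kg/yr) from gross energy intake and Ym (%)."""
    ec = ec or EmissionConstants()
    if gross_energy_mj < 0:
        raise ValueError("gross energy must be >= 0")
    if not (0.0 <= ym_percent <= 100.0):
        raise ValueError("Ym must be a percentage in [0, 100]")
    return gross_energy_mj * (ym_percent / 100.0) / ec.ch4_energy_mj_per_kg


def manure_ch4(vs_kg: float, mcf: float, b0_m3_per_kg: float,
               ec: EmissionConstants | None = None) -> float:
    """Manure-management CH4 (kg/yr) = VS x MCF x B0 x 0.67."""
    ec = ec or EmissionConstants()
    if min(vs_kg, mcf, b0_m3_per_kg) < 0:
        raise ValueError("inputs must be >= 0")
    return vs_kg * mcf * b0_m3_per_kg * ec.ch4_m3_to_kg


def manure_n2o(
    n_excreted_kg: float,
    ef_direct: float,
    volatilization_frac: float = 0.0,
    ef_indirect: float = 0.0,
) -> float:
    """Direct + indirect manure N2O (kg/yr) from N excreted to an MMS."""
    if n_excreted_kg < 0:
        raise ValueError("N excreted must be >= 0")
    direct = n_excreted_kg * ef_direct
    indirect = n_excreted_kg * volatilization_frac * ef_indirect
    return (direct + indirect) * N_TO_N2O


def aquaculture_n2o(n_kg: float, ec: EmissionConstants | None = None) -> float:
    """N2O (kg/yr) from aquaculture: 1.8% of unconsumed + excreted N."""
    ec = ec or EmissionConstants()
    if n_kg < 0:
        raise ValueError("N must be >= 0")
    return n_kg * ec.aquaculture_n2o_frac * N_TO_N2O


def soil_n2o(
    n_applied_kg_by_source: Mapping[str, float],
    moisture: str,
    ec: EmissionConstants | None = None,
    peat_area_ha: float = 0.0,
) -> float:
    """Soil N2O (kg/yr): direct + indirect per fertilizer source, plus the
    area-based term on drained organic (peat) soils, which accrues per ha
    regardless of N applied."""
    ec = ec or EmissionConstants()
    n2o_n = 0.0
    for source, n_kg in n_applied_kg_by_source.items():
        if n_kg < 0:
            raise ValueError("applied N must be >= 0")
        ef = ec.soil_ef(source, moisture)
        n2o_n += n_kg * (
            ef["ef_direct"]
            + ef["frac_volat"] * ef["ef_volat"]
            + ef["frac_leach"] * ef["ef_leach"]
        )
    return n2o_n * N_TO_N2O + peat_area_ha * ec.ef_organic_soil_kg_n2o_per_ha


def grassland_n2o(n_deposited_kg: float, ec: EmissionConstants | None = None,
                  volatilization_frac: float = 0.21) -> float:
    """N2O (kg/yr) from manure deposited on grassland by grazing ruminants."""
    ec = ec or EmissionConstants()
    if n_deposited_kg < 0:
        raise ValueError("N deposited must be >= 0")
    ef = ec.soil_ef("manure", "wet")
    direct = n_deposited_kg * ec.ef_pasture_n2o_direct
    indirect = n_deposited_kg * volatilization_frac * ef["ef_volat"]
    return (direct + indirect) * N_TO_N2O


def compost_emissions(waste_n_kg: float, ec: EmissionConstants | None = None
                      ) -> tuple[float, float]:
    """(N2O kg, CH4 kg) from composting waste with the given N content.

    N2O from the N content; CH4 from the compost carbon pool derived via the
    average compost C:N ratio of 15.
    """
    ec = ec or EmissionConstants()
    if waste_n_kg < 0:
        raise ValueError("waste N must be >= 0")
    n2o = waste_n_kg * ec.compost_n2o_ef * N_TO_N2O
    carbon = waste_n_kg * 15.0
    ch4 = carbon * ec.compost_c_to_ch4
    return n2o, ch4


def transport_emissions(
    flows_tkm: Mapping[str, float],
    ec: EmissionConstants | None = None,
    population_by_country: Mapping[str, float] | None = None,
    cap_kg_per_capita: float = 1500.0,
) -> tuple[float, list[str]]:
    """Total transport CO2 (kg/yr) and the countries exceeding the per-capita
    cap. ``flows_tkm`` maps destination country -> ton-kilometres."""
    ec = ec or EmissionConstants()
    total = 0.0
    flagged: list[str] = []
    for country in sorted(flows_tkm):
        kg = flows_tkm[country] * ec.ef_transport_kg_co2e_per_tkm
        total += kg
        if population_by_country:
            pop = population_by_country.get(country, 0.0)
            if pop > 0 and kg / pop > cap_kg_per_capita + 1e-9:
                flagged.append(country)
    return total, flagged


def fertilizer_production_emissions(
    artificial_n_t: float,
    artificial_p_t: float,
    ec: EmissionConstants | None = None,
) -> float:
    """CO2e (kg/yr) from manufacturing artificial N and P fertilizer."""
    ec = ec or EmissionConstants()
    if artificial_n_t < 0 or artificial_p_t < 0:
        raise ValueError("amounts must be >= 0")
    return (artificial_n_t * 1000.0 * ec.ef_fert_prod_n_kg_co2e_per_kg
            + artificial_p_t * 1000.0 * ec.ef_fert_prod_p_kg_co2e_per_kg)


def total_co2e(inv: GHGInventory, population_fed: float | None = None
               ) -> tuple[float, float | None]:
    """(total kg CO2e/yr, kg CO2e/capita/yr) of an inventory."""
    total = inv.total_co2e()
    if population_fed is None:
        return total, None
    if population_fed <= 0:
        raise ZeroDivisionError("population fed must be > 0")
    return total, total / population_fed
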