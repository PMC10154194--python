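"""Emission formulas and inventory aggregation."""

import pytest
from hypothesis import given, settings, strategies as st

from circfood.ghg import (
    GHGInventory,
    aquaculture_n2o,
    compost_emissions,
    enteric_ch4,
    fertilizer_production_emissions,
    manure_ch4,
    manure_n2o,
    soil_n2o,
    total_co2e,
    transport_emissions,
)
from circfood.instance import EmissionConstants

EC = EmissionConstants()
N2O = 44.0 / 28.0


class TestEnteric:
    def test_zero_intake(self):
        assert enteric_ch4(0.0, 6.5) == 0.0

    def test_unit_case_of_methane_energy_content(self):
        # 55.65 MJ at Ym 100% is exactly one kg of methane
        assert enteric_ch4(55.65, 100.0) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert enteric_ch4(10000.0, 6.5) == pytest.approx(
            10000.0 * 0.065 / 55.65)

    def test_ym_range_enforced(self):
        with pytest.raises(ValueError):
            enteric_ch4(1.0, 120.0)


class TestManure:
    def test_m3_to_kg_unit_case(self):
        assert manure_ch4(1.0, 1.0, 1.0) == pytest.approx(0.67)

    def test_ch4_arithmetic(self):
        assert manure_ch4(100.0, 0.1, 0.24) == pytest.approx(1.608)

    def test_n2o_direct(self):
        assert manure_n2o(100.0, 0.01) == pytest.approx(100 * 0.01 * N2O)

    def test_n2o_indirect_adds_monotonically(self):
        base = manure_n2o(100.0, 0.01)
        with_ind = manure_n2o(100.0, 0.01, 0.3, 0.01)
        assert with_ind > base


class TestAquacultureAndSoil:
    def test_aquaculture_stated_fraction(self):
        assert aquaculture_n2o(100.0) == pytest.approx(100 * 0.018 * N2O)

    def test_aquaculture_linearity(self):
        assert aquaculture_n2o(7.0) == pytest.approx(7 * aquaculture_n2o(1.0))

    def test_soil_composite_ef(self):
        ec = EmissionConstants(ef_soil={"artificial|wet": {
            "ef_direct": 0.01, "frac_volat": 0.0, "ef_volat": 0.0,
            "frac_leach": 0.0, "ef_leach": 0.0}})
        out = soil_n2o({"artificial": 1000.0}, "wet", ec)
        assert out == pytest.approx(1000 * 0.01 * N2O)

    def test_peat_term_is_area_based(self):
        out0 = soil_n2o({}, "wet", EC, peat_area_ha=10.0)
        out1 = soil_n2o({"artificial": 1000.0}, "wet", EC, peat_area_ha=10.0)
        base = soil_n2o({"artificial": 1000.0}, "wet", EC)
        assert out0 == pytest.approx(10 * EC.ef_organic_soil_kg_n2o_per_ha)
        assert out1 == pytest.approx(base + out0)


class TestCompostTransportFertilizer:
    def test_compost_zero(self):
        assert compost_emissions(0.0) == (0.0, 0.0)

    def test_compost_carbon_via_cn_ratio(self):
        n2o, ch4 = compost_emissions(10.0)
        assert ch4 == pytest.approx(10.0 * 15.0 * EC.compost_c_to_ch4)
        assert n2o == pytest.approx(10.0 * EC.compost_n2o_ef * N2O)

    def test_transport_no_flows(self):
        total, flagged = transport_emissions({})
        assert total == 0.0 and flagged == []

    def test_transport_arithmetic(self):
        total, _ = transport_emissions({"C1": 10.0 * 500.0})
        assert total == pytest.approx(500.0)

    def test_transport_cap_flag(self):
        # 1,501 kg per capita trips the cap; 1,500 does not (inclusive)
        pop = {"C1": 1.0}
        _, over = transport_emissions({"C1": 15010.0}, EC, pop)
        assert over == ["C1"]
        _, ok = transport_emissions({"C1": 15000.0}, EC, pop)
        assert ok == []

    def test_fertilizer_production(self):
        assert fertilizer_production_emissions(1.0, 0.0) == pytest.approx(5000.0)
        both = fertilizer_production_emissions(1.0, 1.0)
        assert both == pytest.approx(
            fertilizer_production_emissions(1.0, 0.0)
            + fertilizer_production_emissions(0.0, 1.0))


class TestAggregation:
    def test_gwp_weights(self):
        inv = GHGInventory()
        inv.add("enteric", "CH4", 1.0)
        assert inv.total_co2e() == pytest.approx(28.0)
        inv2 = GHGInventory()
        inv2.add("soil_N2O", "N2O", 1.0)
        assert inv2.total_co2e() == pytest.approx(265.0)

    def test_empty_inventory_is_zero(self):
        assert GHGInventory().total_co2e() == 0.0

    def test_total_equals_sum_of_categories(self):
        inv = GHGInventory()
        inv.add("enteric", "CH4", 2.0)
        inv.add("soil_N2O", "N2O", 0.5)
        inv.add("transport", "CO2", 100.0)
        cats = {c for (c, g) in inv.entries}
        assert inv.total_co2e() == pytest.approx(
            sum(inv.by_category_co2e(c) for c in cats))

    def test_per_capita(self):
        inv = GHGInventory()
        inv.add("transport", "CO2", 1000.0)
        total, per_cap = total_co2e(inv, 10.0)
        assert (total, per_cap) == (1000.0, 100.0)
        with pytest.raises(ZeroDivisionError):
            total_co2e(inv, 0.0)

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(0.1, 100.0), activity=st.floats(0.0, 1e6))
    def test_operations_homogeneous_degree_one(self, scale, activity):
        for fn in (lambda a: enteric_ch4(a, 6.5),
                   lambda a: manure_ch4(a, 0.1, 0.24),
                   lambda a: aquaculture_n2o(a),
                   lambda a: soil_n2o({"manure": a}, "dry")):
            assert fn(scale * activity) == pytest.approx(
                scale * fn(activity), rel=1e-9, abs=1e-12)
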