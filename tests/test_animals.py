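"""Herd coupling, ration feasibility, manure balance and fisheries."""

import pytest

from circfood.animals import (
    animal_outputs,
    fishery_supply,
    manure_excretion,
    ration_check,
    ration_volatile_solids,
    stock_requirements,
)
from circfood.instance import AnimalSystem, FeedItem, FishStock


def _system(**kw):
    base = dict(
        system_id="pigs", species="pig", productivity_level="high",
        output_t_per_unit=0.1,
        requirement_per_t_product={"energy_mj_per_t": 30000.0,
                                   "dig_protein_kg_per_t": 300.0},
        intake_capacity_t_dm=0.3,
        parent_stock_ratio=0.1, repro_stock_ratio=0.2,
        aux_requirement_per_unit={"energy_mj_per_t": 10000.0,
                                  "dig_protein_kg_per_t": 100.0},
        aux_intake_capacity_t_dm=1.0,
        n_retention_frac=0.3, p_retention_frac=0.3,
    )
    base.update(kw)
    return AnimalSystem(**base)


class TestStockRequirements:
    def test_zero_target_all_zero(self):
        req = stock_requirements(0.0, _system())
        assert req.producing_units == 0.0
        assert req.intake_capacity_t_dm == 0.0
        assert all(v == 0.0 for v in req.requirements.values())

    def test_auxiliary_ratio_arithmetic(self):
        # 100 producing units at 0.1 t each -> 10 t target output
        req = stock_requirements(10.0, _system())
        assert req.producing_units == pytest.approx(100.0)
        assert req.parent_units == pytest.approx(10.0)
        assert req.repro_units == pytest.approx(20.0)

    def test_linearity_in_target(self):
        r1 = stock_requirements(5.0, _system())
        r2 = stock_requirements(10.0, _system())
        assert r2.producing_units == pytest.approx(2 * r1.producing_units)
        assert r2.intake_capacity_t_dm == pytest.approx(
            2 * r1.intake_capacity_t_dm)
        for nut in r1.requirements:
            assert r2.requirements[nut] == pytest.approx(
                2 * r1.requirements[nut])

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            stock_requirements(-1.0, _system())


class TestRationCheck:
    FEEDS = {
        "grain": FeedItem("grain", "fodder_crop",
                          {"dm_frac": 0.9, "energy_mj_per_t": 12000.0,
                           "dig_protein_kg_per_t": 100.0}),
        "waste": FeedItem("waste", "food_waste",
                          {"dm_frac": 0.25, "energy_mj_per_t": 3000.0,
                           "dig_protein_kg_per_t": 30.0},
                          legality={"dairy": False, "beef": False,
                                    "pig": True}),
    }

    def test_food_waste_illegal_for_dairy(self):
        cow = _system(system_id="cows", species="dairy", ym_percent=6.0)
        stocks = stock_requirements(1.0, cow)
        out = ration_check({"waste": 10.0}, cow, stocks, self.FEEDS)
        assert any(f.kind == "illegal_item" for f in out)

    def test_exact_boundary_is_feasible(self):
        sys = _system(parent_stock_ratio=0.0, repro_stock_ratio=0.0)
        stocks = stock_requirements(1.0, sys)
        # requirements per t: 30,000 MJ & 300 kg; capacity 3 t DM
        grain_t = stocks.intake_capacity_t_dm / 0.9
        feeds = {"grain": FeedItem("grain", "fodder_crop", {
            "dm_frac": 0.9,
            "energy_mj_per_t": 30000.0 / grain_t,
            "dig_protein_kg_per_t": 300.0 / grain_t})}
        assert ration_check({"grain": grain_t}, sys, stocks, feeds) == []

    def test_deficit_names_the_nutrient(self):
        sys = _system(parent_stock_ratio=0.0, repro_stock_ratio=0.0)
        stocks = stock_requirements(1.0, sys)
        out = ration_check({"grain": 30000.0 / 12000.0 * 0.99}, sys, stocks,
                           self.FEEDS)
        assert any(f.kind == "nutrient_deficit" and "energy" in f.detail
                   for f in out)

    def test_unknown_feed_rejected(self):
        sys = _system()
        stocks = stock_requirements(1.0, sys)
        with pytest.raises(KeyError):
            ration_check({"kelp": 1.0}, sys, stocks, self.FEEDS)


class TestOutputsAndManure:
    def test_outputs_zero_and_linear(self):
        sys = _system(product_composition={"protein": 0.18})
        assert animal_outputs(0.0, sys)[0] == 0.0
        t1, n1 = animal_outputs(10.0, sys)
        t2, n2 = animal_outputs(20.0, sys)
        assert t1 == pytest.approx(1.0)
        assert n1["protein"] == pytest.approx(1e6 * 0.18)
        assert t2 == pytest.approx(2 * t1)
        assert n2["protein"] == pytest.approx(2 * n1["protein"])

    def test_excretion_is_intake_minus_retention(self):
        split = manure_excretion(100.0, 20.0, 0.3, 0.5, grazing_share=0.0)
        assert split.n_to_mms_kg == pytest.approx(70.0)
        assert split.p_to_mms_kg == pytest.approx(10.0)
        assert split.n_on_grassland_kg == 0.0

    def test_full_retention_no_excretion(self):
        split = manure_excretion(100.0, 20.0, 1.0, 1.0, 0.5)
        assert split.n_to_mms_kg == 0.0
        assert split.n_on_grassland_kg == 0.0

    def test_full_grazing_everything_on_grassland(self):
        split = manure_excretion(100.0, 20.0, 0.3, 0.5, grazing_share=1.0)
        assert split.n_to_mms_kg == 0.0
        assert split.n_on_grassland_kg == pytest.approx(70.0)

    def test_retention_above_one_rejected(self):
        with pytest.raises(ValueError):
            manure_excretion(1.0, 1.0, 1.1, 0.0, 0.0)

    def test_volatile_solids_from_digestibility(self):
        feeds = {"grain": FeedItem("grain", "fodder_crop",
                                   {"dm_frac": 0.9, "dig_om_frac": 0.8})}
        # 10 t x 0.9 DM x 0.2 indigestible x 0.92 ash correction, in kg
        vs = ration_volatile_solids({"grain": 10.0}, "pig", feeds)
        assert vs == pytest.approx(10.0 * 0.9 * 0.2 * 0.92 * 1000.0)


class TestFisheries:
    STOCKS = {"cod": FishStock("cod", "wild_mix", {"C1": 100.0},
                               edible_frac=0.6)}

    def test_zero_quota(self):
        out = fishery_supply({("cod", "C1"): 0.0}, self.STOCKS)
        assert out[("cod", "C1")] == (0.0, 0.0)

    def test_edible_byproduct_split_at_cap(self):
        out = fishery_supply({("cod", "C1"): 100.0}, self.STOCKS)
        edible, bp = out[("cod", "C1")]
        assert edible == pytest.approx(60.0)
        assert bp == pytest.approx(40.0)

    def test_landings_clipped_to_msy(self):
        out = fishery_supply({("cod", "C1"): 120.0}, self.STOCKS)
        assert sum(out[("cod", "C1")]) == pytest.approx(100.0)
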