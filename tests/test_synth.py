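"""Synthetic instance generation: determinism, structure, known optima."""

import pytest

import circfood as cf
from circfood.instance import instance_to_dict
from circfood.nutrients import ANIMAL_GROUPS, FOOD_GROUPS
from circfood.synth import PLANT_GROUPS


class TestGenerator:
    def test_deterministic_for_fixed_seed(self, default_instance):
        again = cf.generate_instance(seed=1)
        assert instance_to_dict(again) == instance_to_dict(default_instance)

    def test_different_seeds_differ(self, default_instance):
        other = cf.generate_instance(seed=2)
        assert instance_to_dict(other) != instance_to_dict(default_instance)

    def test_passes_validation(self, default_instance):
        assert cf.validate_instance(default_instance) == []

    def test_b12_zero_for_plants_positive_for_animal_foods(
            self, default_instance):
        inst = default_instance
        for f in inst.food_ids():
            b12 = inst.food_composition_of(f).get("vitamin_b12", 0.0)
            if inst.food_group_of(f) in ANIMAL_GROUPS:
                assert b12 > 0, f
            else:
                assert b12 == 0, f

    def test_every_plant_group_covered(self, default_instance):
        groups = {c.food_group for c in default_instance.crops.values()}
        assert set(PLANT_GROUPS) <= groups

    def test_yields_vary_across_zones(self, default_instance):
        crop = default_instance.crops["grains_1"]
        ys = list(crop.yield_by_zone.values())
        assert len(set(ys)) == len(ys)

    def test_stage_waste_fracs_in_open_interval(self, default_instance):
        for f in default_instance.food_ids():
            fracs = default_instance.residual_params.stage_fracs_for(f)
            for stage, frac in fracs.items():
                assert 0.0 < frac < 0.3, (f, stage)

    def test_consumption_waste_pool_positive(self, solved_presets):
        _, sol = solved_presets["cirhealth"]
        waste = (sum(sol.waste_to_feed_t.values())
                 + sum(sol.waste_to_compost_t.values()))
        assert waste > 0

    def test_grass_feeds_only_for_ruminants(self, default_instance):
        for item in default_instance.feed_items.values():
            if item.origin != "grass":
                continue
            for s in default_instance.animal_systems.values():
                if not s.is_ruminant:
                    assert not item.legal_for(s.species)

    def test_tcf_mass_fractions_sum_at_most_one(self, default_instance):
        for entry in default_instance.residual_params.tcf.values():
            total = entry["main_fraction"] + sum(entry["byproducts"].values())
            assert total <= 1.0 + 1e-12

    def test_baseline_scenario_is_feasible(self, solved_presets):
        _, sol = solved_presets["agribase"]
        assert sol.status == "optimal"

    def test_undersized_requests_fail_loudly(self):
        with pytest.raises(cf.GenerationError):
            cf.generate_instance(n_crops=5, seed=1)
        with pytest.raises(cf.GenerationError):
            cf.generate_instance(n_zones=1, n_countries=2, seed=1)


class TestKnownOptimum:
    def test_expected_areas_nonnegative_and_cover_minima(self, known_optimum):
        inst, exp = known_optimum
        assert all(a >= 0 for a in exp.areas.values())
        comp = inst.crops["dominant"].food_composition
        for nid, spec in inst.nutrient_specs.items():
            if spec.min_per_capita_day:
                supplied = exp.diet_g_day * comp[nid]
                assert supplied >= spec.min_per_capita_day - 1e-9
        binding = inst.nutrient_specs[exp.binding_nutrient]
        assert exp.diet_g_day * comp[exp.binding_nutrient] == pytest.approx(
            binding.min_per_capita_day)

    def test_deterministic(self, known_optimum):
        inst, exp = known_optimum
        inst2, exp2 = cf.generate_known_optimum_instance(7)
        assert exp2 == exp
        assert instance_to_dict(inst2) == instance_to_dict(inst)


class TestScalePopulation:
    def test_factor_one_is_identity(self, default_instance):
        scaled = cf.scale_population(default_instance, 1.0)
        assert instance_to_dict(scaled) == instance_to_dict(default_instance)

    def test_only_population_scaled(self, default_instance):
        scaled = cf.scale_population(default_instance, 2.0)
        for k in default_instance.countries:
            assert scaled.population_by_country[k] == pytest.approx(
                2 * default_instance.population_by_country[k])
        assert scaled.current_areas == default_instance.current_areas
        assert scaled.current_sludge_t == default_instance.current_sludge_t

    @pytest.mark.parametrize("bad", [0.0, -2.0])
    def test_nonpositive_factor_rejected(self, default_instance, bad):
        with pytest.raises(ValueError):
            cf.scale_population(default_instance, bad)
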