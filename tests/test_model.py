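"""Problem assembly, solving, verification and scenario reports."""

import copy
import dataclasses
import pytest

import circfood as cf
from circfood.model import ScenarioConfig


class TestScenarioConfig:
    def test_baseline_requires_fixed_areas(self):
        with pytest.raises(ValueError):
            ScenarioConfig("x", "current_protein_by_food_group",
                           "calibrate_baseline", fixed_current_areas=False)

    def test_unknown_modes_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig("x", "freestyle", "min_agricultural_land")
        with pytest.raises(ValueError):
            ScenarioConfig("x", "efsa_plus_eat_lancet", "max_profit")


class TestBuildProblem:
    def test_healthy_diet_families(self, default_instance):
        spec = cf.build_problem(default_instance, cf.cirhealth())
        fams = set(spec.families_present)
        assert {"nutrition", "food_group", "land", "rotation", "suitability",
                "feed", "fertilizer", "waste", "fishery", "in_country",
                "transport"} <= fams
        assert "protein_match" not in fams

    def test_protein_match_families(self, default_instance):
        spec = cf.build_problem(default_instance, cf.ciragri())
        fams = set(spec.families_present)
        assert "protein_match" in fams
        assert "nutrition" not in fams
        assert "food_group" not in fams

    def test_counts_reported(self, default_instance):
        spec = cf.build_problem(default_instance, cf.cirhealth())
        assert spec.n_vars > 100
        assert spec.n_constraints > 100

    def test_mismatch_raises(self):
        tiny = cf.generate_tiny_instance(1)  # no current-supply data
        with pytest.raises(ValueError, match="current_supply"):
            cf.build_problem(tiny, cf.ciragri())

    def test_baseline_fixes_areas_to_current(self, default_instance,
                                             solved_presets):
        _, sol = solved_presets["agribase"]
        for cid, zmap in default_instance.current_areas.items():
            for zid, a in zmap.items():
                assert sol.area.get((cid, zid), 0.0) == pytest.approx(
                    a, rel=1e-9, abs=1e-9)


class TestSolve:
    def test_known_optimum_recovered(self, known_optimum):
        inst, exp = known_optimum
        sol = cf.solve(cf.build_problem(inst, cf.cirhealth()))
        assert sol.objective_value == pytest.approx(exp.objective_ha,
                                                    rel=1e-6)
        for key, a in exp.areas.items():
            assert sol.area.get(key, 0.0) == pytest.approx(a, rel=1e-6)

    def test_yield_perturbation_flips_optimal_crop(self, known_optimum):
        inst, _ = known_optimum
        pert = copy.deepcopy(inst)
        pert.crops["dominant"].yield_by_zone["Z1"] /= 10.0
        sol = cf.solve(cf.build_problem(pert, cf.cirhealth()))
        assert set(c for (c, _z) in sol.area) == {"dominated"}

    def test_forced_infeasibility_names_nutrition(self, default_instance):
        bad = copy.deepcopy(default_instance)
        bad.nutrient_specs["vitamin_b12"] = dataclasses.replace(
            bad.nutrient_specs["vitamin_b12"], min_per_capita_day=1e9)
        with pytest.raises(cf.InfeasibleProblemError) as err:
            cf.solve(cf.build_problem(bad, cf.cirhealth()))
        assert "nutrition" in err.value.families

    def test_resolve_is_deterministic(self, default_instance):
        s1 = cf.solve(cf.build_problem(default_instance, cf.cirhealth()))
        s2 = cf.solve(cf.build_problem(default_instance, cf.cirhealth()))
        assert s1.area == s2.area
        assert s1.diet == s2.diet
        assert s1.objective_value == s2.objective_value


class TestVerification:
    @pytest.mark.parametrize("name", ["agribase", "ciragri", "cirhealth",
                                      "cirpop"])
    def test_validators_empty_on_solver_output(self, default_instance,
                                               solved_presets, name):
        scen, sol = solved_presets[name]
        assert cf.verify_solution(default_instance, scen, sol) == []

    def test_validators_empty_on_second_seed(self):
        inst = cf.generate_instance(seed=5)
        for preset in (cf.ciragri, cf.cirhealth):
            scen = preset()
            sol = cf.solve(cf.build_problem(inst, scen))
            assert cf.verify_solution(inst, scen, sol) == []

    def test_no_waste_in_ruminant_rations(self, default_instance,
                                          solved_presets):
        for name in ("ciragri", "cirhealth", "cirpop"):
            _, sol = solved_presets[name]
            for (fid, sid, _k), t in sol.feed_alloc.items():
                system = default_instance.animal_systems[sid]
                if system.is_ruminant:
                    item = default_instance.feed_items[fid]
                    assert item.origin != "food_waste" or t == 0.0

    def test_waste_feed_within_share(self, default_instance, solved_presets):
        inst = default_instance
        frac = inst.residual_params.waste_to_feed_frac
        for name in ("ciragri", "cirhealth"):
            _, sol = solved_presets[name]
            for k in inst.countries:
                cw = sum(
                    sol.delivered.get((f, k), 0.0)
                    * inst.residual_params.stage_fracs_for(f)["consumption"]
                    for f in inst.food_ids())
                assert sol.waste_to_feed_t.get(k, 0.0) <= frac * cw + 1e-6


class TestStructuralProperties:
    def test_removing_all_feed_stops_the_species(self, default_instance):
        inst = copy.deepcopy(default_instance)
        for item in inst.feed_items.values():
            item.legality["pig"] = False
        sol = cf.solve(cf.build_problem(inst, cf.cirhealth()))
        pig_units = sum(u for (sid, _k), u in sol.animals.items()
                        if inst.animal_systems[sid].species == "pig")
        assert pig_units == pytest.approx(0.0, abs=1e-9)

    def test_circular_land_at_most_baseline_land(self, solved_presets):
        base_land = solved_presets["agribase"][1].total_land_ha()
        for name in ("ciragri", "cirhealth"):
            assert solved_presets[name][1].total_land_ha() <= base_land + 1e-6

    def test_max_population_exceeds_current_when_land_slack(
            self, solved_presets):
        # the land-minimizing healthy-diet scenario leaves most land unused,
        # so the population-maximizing run must feed at least the current one
        _, minland = solved_presets["cirhealth"]
        _, maxpop = solved_presets["cirpop"]
        assert maxpop.population_multiplier >= 1.0 - 1e-9


class TestScenarioReport:
    def test_report_tables(self, default_instance):
        rep = cf.run_scenario(default_instance, cf.cirhealth())
        assert rep.violations == []
        assert rep.total_land_ha == pytest.approx(
            rep.solution.total_land_ha())
        assert set(rep.land_by_type["land_type"]) == {"cropland", "grassland"}
        assert rep.total_co2e_kg > 0
        assert rep.co2e_per_capita_kg > 0
        assert len(rep.nutrient_intake) == 42

    def test_ghg_total_matches_inventory(self, solved_presets):
        _, sol = solved_presets["ciragri"]
        inv = sol.ghg
        cats = {c for (c, _g) in inv.entries}
        assert inv.total_co2e() == pytest.approx(
            sum(inv.by_category_co2e(c) for c in cats))


class TestPercentChange:
    def test_identity_is_zero(self):
        assert cf.percent_change(7.0, 7.0) == 0

    def test_sign_convention(self):
        assert cf.percent_change(100.0, 50.0) == -50
        assert cf.percent_change(100.0, 150.0) == 50

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cf.percent_change(0.0, 1.0)


class TestOracle:
    def test_two_crop_agreement(self):
        inst = cf.generate_tiny_instance(11)
        scen = cf.cirhealth()
        sol = cf.solve(cf.build_problem(inst, scen))
        oracle = cf.brute_force_optimum(inst, scen, grid_g_day=2.0,
                                        max_g_day=1800.0)
        assert oracle == pytest.approx(sol.objective_value, rel=0.01)

    def test_infeasible_agreement(self):
        inst = cf.generate_tiny_instance(12)
        inst.nutrient_specs["vitamin_b12"] = dataclasses.replace(
            inst.nutrient_specs["vitamin_b12"], min_per_capita_day=1.0)
        scen = cf.cirhealth()
        with pytest.raises(cf.InfeasibleProblemError):
            cf.solve(cf.build_problem(inst, scen))
        assert cf.brute_force_optimum(inst, scen, grid_g_day=10.0) is None

    def test_grid_refinement_converges_toward_solver(self):
        inst = cf.generate_tiny_instance(13)
        scen = cf.cirhealth()
        sol = cf.solve(cf.build_problem(inst, scen))
        coarse = cf.brute_force_optimum(inst, scen, grid_g_day=40.0)
        fine = cf.brute_force_optimum(inst, scen, grid_g_day=4.0)
        # grid optima over-estimate and tighten monotonically with refinement
        assert sol.objective_value <= fine + 1e-9 <= coarse + 1e-9
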