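"""Instance schema, validation and serialization round trips."""

import copy

import pytest

import circfood as cf
from circfood.instance import (
    DanglingReferenceError,
    InstanceParseError,
    Solution,
    instance_to_dict,
    read_solution,
)


class TestInstanceIO:
    def test_round_trip_identity(self, default_instance, instance_file):
        loaded = cf.load_instance(instance_file)
        assert instance_to_dict(loaded) == instance_to_dict(default_instance)

    def test_fixture_shape(self, instance_file):
        inst = cf.load_instance(instance_file)
        assert len(inst.zones) == 3
        assert len(inst.countries) == 2
        assert len(inst.animal_systems) == 4
        assert sum(c.is_food_crop for c in inst.crops.values()) == 10

    def test_unknown_keys_rejected(self, tmp_path, default_instance):
        import yaml

        data = instance_to_dict(default_instance)
        data["zones"]["Z1"]["surprise"] = 1
        p = tmp_path / "bad.yaml"
        p.write_text(yaml.safe_dump(data))
        with pytest.raises(InstanceParseError, match="surprise"):
            cf.load_instance(p)

    def test_dangling_reference_named(self, tmp_path, default_instance):
        import yaml

        data = instance_to_dict(default_instance)
        data["crops"]["grains_1"]["feed_value_id"] = "missing_feed"
        p = tmp_path / "bad.yaml"
        p.write_text(yaml.safe_dump(data))
        with pytest.raises(DanglingReferenceError, match="missing_feed"):
            cf.load_instance(p)

    def test_parse_error_on_garbage(self, tmp_path):
        p = tmp_path / "broken.yaml"
        p.write_text("zones: [unclosed")
        with pytest.raises(InstanceParseError):
            cf.load_instance(p)


class TestValidation:
    def test_clean_instance_has_empty_report(self, default_instance):
        assert cf.validate_instance(default_instance) == []

    def test_rotation_frequency_bound(self, default_instance):
        inst = copy.deepcopy(default_instance)
        inst.crops["grains_1"].rotation_max_frequency = 1.5
        report = cf.validate_instance(inst)
        assert any("rotation_max_frequency" in v.rule for v in report)

    def test_food_waste_illegal_for_ruminants(self, default_instance):
        inst = copy.deepcopy(default_instance)
        inst.feed_items["food_waste"].legality["dairy"] = True
        report = cf.validate_instance(inst)
        assert any("ruminant" in v.rule for v in report)

    def test_validation_is_total(self, default_instance):
        # pathological but parseable values produce findings, not exceptions
        inst = copy.deepcopy(default_instance)
        inst.zones["Z1"].area_by_land_type["cropland"] = -5.0
        inst.zones["Z2"].climate_class = "lunar"
        inst.animal_systems["pig"].ym_percent = 6.0
        del inst.nutrient_specs["energy"]
        report = cf.validate_instance(inst)
        assert len(report) >= 4


class TestSolutionIO:
    def test_empty_solution_headers_only(self, tmp_path):
        out = tmp_path / "empty"
        cf.write_solution(Solution(), out)
        area = (out / "area.csv").read_text().strip().splitlines()
        assert area == ["crop,zone,area_ha"]

    def test_round_trip_sums(self, tmp_path, solved_presets):
        _, sol = solved_presets["cirhealth"]
        out = tmp_path / "sol"
        cf.write_solution(sol, out)
        back = read_solution(out)
        for attr in ("area", "grass_area", "feed_alloc", "flows", "diet"):
            a = sum(getattr(sol, attr).values())
            b = sum(getattr(back, attr).values())
            assert b == pytest.approx(a, rel=1e-8)
        assert back.objective_value == pytest.approx(sol.objective_value)

    def test_writes_are_byte_identical(self, tmp_path, solved_presets):
        _, sol = solved_presets["ciragri"]
        out1, out2 = tmp_path / "a", tmp_path / "b"
        cf.write_solution(sol, out1)
        cf.write_solution(sol, out2)
        for f in sorted(out1.iterdir()):
            assert f.read_bytes() == (out2 / f.name).read_bytes()
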