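"""Rotation shares, crop suitability and fertilizer balances."""

import pytest

import circfood as cf
from circfood.cropping import (
    crop_nutrient_removal,
    fertilizer_requirement,
    fertilizer_supply_balance,
    rotation_share,
    suitable_crops,
)
from circfood.instance import Crop, EmissionConstants, Zone


@pytest.mark.parametrize(
    "freq, share",
    [(0.25, 0.25), (4, 0.25), (1.0, 1.0), (1, 1.0), (1 / 6, 1 / 6), (6, 1 / 6)],
)
def test_rotation_share(freq, share):
    assert rotation_share(freq) == pytest.approx(share)


@pytest.mark.parametrize("bad", [0.0, -1.0, 2.5])
def test_rotation_share_rejects(bad):
    with pytest.raises(ValueError):
        rotation_share(bad)


class TestSuitability:
    def test_unsuitable_crops_excluded(self, default_instance):
        zone = default_instance.zones["Z1"]
        caps = suitable_crops(zone, default_instance)
        assert all(zone.zone_id in default_instance.crops[c].yield_by_zone
                   for c in caps)

    def test_minor_crop_capped_at_current_acreage(self, default_instance):
        import copy

        inst = copy.deepcopy(default_instance)
        inst.crops["other_1"].acreage_cap_by_zone = {"Z1": 42.0}
        caps = suitable_crops(inst.zones["Z1"], inst)
        assert caps["other_1"] == pytest.approx(42.0)

    def test_ordinary_crop_uses_rotation_cap(self, default_instance):
        zone = default_instance.zones["Z1"]
        caps = suitable_crops(zone, default_instance)
        crop = default_instance.crops["grains_1"]
        expected = rotation_share(crop.rotation_max_frequency) * zone.cropland_ha()
        assert caps["grains_1"] == pytest.approx(expected)


class TestRemovalAndRequirement:
    CROP = Crop("c", "other", {"Z": 5.0}, 1.0, residue_to_product_ratio=1.0,
                n_conc_product=10.0, p_conc_product=3.0,
                n_conc_residue=4.0, p_conc_residue=1.0)
    ZONE = Zone("Z", "C1", {"cropland": 100.0, "temporary_grassland": 0.0,
                            "permanent_pasture": 0.0, "rangeland": 0.0},
                "temperate_wet", "other")

    def test_zero_area_zero_removal(self):
        assert crop_nutrient_removal(self.CROP, "Z", 0.0) == {"N": 0.0, "P": 0.0}

    def test_hand_example_p(self):
        # 1 ha x 5 t x (3 + 1x1) kg P/t = 20 kg P
        assert crop_nutrient_removal(self.CROP, "Z", 1.0)["P"] == pytest.approx(20.0)

    def test_linearity_in_area(self):
        r1 = crop_nutrient_removal(self.CROP, "Z", 1.5)
        r2 = crop_nutrient_removal(self.CROP, "Z", 3.0)
        assert r2["N"] == pytest.approx(2 * r1["N"])

    def test_unsuitable_zone_rejected(self):
        with pytest.raises(ValueError):
            crop_nutrient_removal(self.CROP, "elsewhere", 1.0)

    def test_p_requirement_adds_unavoidable_loss(self):
        req = fertilizer_requirement(self.CROP, self.ZONE, 1.0,
                                     EmissionConstants())
        assert req["P"] == pytest.approx(20.0 * 1.125)

    def test_n_requirement_at_least_removal(self):
        req = fertilizer_requirement(self.CROP, self.ZONE, 1.0,
                                     EmissionConstants())
        removal = crop_nutrient_removal(self.CROP, "Z", 1.0)
        assert req["N"] >= removal["N"]

    def test_divisor_loss_mode_is_larger(self):
        mult = fertilizer_requirement(self.CROP, self.ZONE, 1.0,
                                      EmissionConstants())
        div = fertilizer_requirement(self.CROP, self.ZONE, 1.0,
                                     EmissionConstants(), loss_mode="divisor")
        assert div["P"] == pytest.approx(20.0 / 0.875)
        assert div["P"] > mult["P"]
        assert div["N"] > mult["N"]

    def test_residue_offset_credits_field_nutrients(self):
        req = fertilizer_requirement(self.CROP, self.ZONE, 1.0,
                                     EmissionConstants(),
                                     residues_offset=True)
        # only the harvested product (5 t x 3 kg P/t) remains in the base
        assert req["P"] == pytest.approx(15.0 * 1.125)

    def test_zero_removal_zero_requirement(self):
        req = fertilizer_requirement(self.CROP, self.ZONE, 0.0,
                                     EmissionConstants())
        assert req == {"N": 0.0, "P": 0.0}


class TestSupplyBalance:
    RATIOS = {"manure": 5.0}

    def test_exact_cover_is_empty(self):
        reqs = {("c", "z"): {"N": 10.0, "P": 2.0}}
        apps = {("manure", "c", "z"): (10.0, 0.0),
                ("artificial", "c", "z"): (0.0, 2.0)}
        assert fertilizer_supply_balance(apps, reqs, self.RATIOS) == []

    def test_organic_p_follows_fixed_ratio(self):
        # an organic source applied for N delivers P = N / ratio regardless
        # of the declared P entry
        reqs = {("c", "z"): {"N": 10.0, "P": 2.0}}
        apps = {("manure", "c", "z"): (10.0, 99.0)}
        out = fertilizer_supply_balance(apps, reqs, self.RATIOS)
        assert [d.nutrient for d in out] == []  # P = 10/5 = 2 exactly

    def test_deficit_reported_when_organics_insufficient(self):
        reqs = {("c", "z"): {"N": 10.0, "P": 5.0}}
        apps = {("manure", "c", "z"): (10.0, 0.0)}
        out = fertilizer_supply_balance(apps, reqs, self.RATIOS)
        assert [(d.nutrient, d.deficit_kg) for d in out] == [("P", 3.0)]

    def test_negative_application_rejected(self):
        with pytest.raises(ValueError):
            fertilizer_supply_balance({("manure", "c", "z"): (-1.0, 0.0)},
                                      {}, self.RATIOS)
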