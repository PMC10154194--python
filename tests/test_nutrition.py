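"""Diet nutrient accounting and the three dietary constraint families."""

import pytest
from hypothesis import given, settings, strategies as st

from circfood.instance import FoodGroupBound, NutrientSpec
from circfood.nutrition import (
    apply_waste_chain,
    diet_nutrients,
    food_group_violations,
    nutrient_bound_violations,
    protein_supply_match,
    zero_nutrient_vector,
)
from circfood.nutrients import NUTRIENTS


def _comp(**kw):
    base = {n: 0.0 for n in NUTRIENTS}
    base.update(kw)
    return base


class TestDietNutrients:
    def test_empty_diet_is_zero_vector(self):
        assert diet_nutrients({}, {}) == zero_nutrient_vector()

    def test_linearity(self):
        comp = {"bread": _comp(protein=0.2)}
        vec = diet_nutrients({"bread": 100.0}, comp)
        assert vec["protein"] == pytest.approx(20.0)

    def test_missing_composition_names_food(self):
        with pytest.raises(KeyError, match="mystery"):
            diet_nutrients({"mystery": 1.0}, {})

    @settings(derandomize=True, max_examples=30)
    @given(
        a=st.floats(0, 500), b=st.floats(0, 500),
        p1=st.floats(0, 1), p2=st.floats(0, 1),
    )
    def test_additivity(self, a, b, p1, p2):
        comp = {"x": _comp(protein=p1, energy=2.0),
                "y": _comp(protein=p2, energy=1.0)}
        v1 = diet_nutrients({"x": a}, comp)
        v2 = diet_nutrients({"y": b}, comp)
        v12 = diet_nutrients({"x": a, "y": b}, comp)
        for n in ("protein", "energy"):
            assert v12[n] == pytest.approx(v1[n] + v2[n], abs=1e-9)


class TestWasteChain:
    def test_zero_fractions_identity(self):
        intake, losses = apply_waste_chain({"apple": 100.0}, {})
        assert intake["apple"] == 100.0
        assert sum(losses["apple"].values()) == 0.0

    def test_two_stage_hand_example(self):
        fracs = {"apple": {"post_harvest": 0.1, "consumption": 0.1}}
        intake, losses = apply_waste_chain({"apple": 100.0}, fracs)
        assert intake["apple"] == pytest.approx(81.0)
        assert losses["apple"]["post_harvest"] == pytest.approx(10.0)
        assert losses["apple"]["consumption"] == pytest.approx(9.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        supply=st.floats(0, 1e6),
        fr=st.lists(st.floats(0, 0.99), min_size=4, max_size=4),
    )
    def test_mass_conservation(self, supply, fr):
        stages = ("post_harvest", "processing", "distribution", "consumption")
        fracs = {"x": dict(zip(stages, fr))}
        intake, losses = apply_waste_chain({"x": supply}, fracs)
        assert intake["x"] + sum(losses["x"].values()) == pytest.approx(
            supply, rel=1e-12, abs=1e-9)

    def test_fraction_at_one_rejected(self):
        with pytest.raises(ValueError):
            apply_waste_chain({"x": 1.0}, {"x": {"consumption": 1.0}})


class TestNutrientBounds:
    def _specs(self):
        specs = {n: NutrientSpec(n, "u") for n in NUTRIENTS}
        specs["energy"] = NutrientSpec("energy", "kcal", 2000.0, 2600.0)
        specs["protein"] = NutrientSpec("protein", "g", 50.0, None)
        return specs

    def test_boundary_is_inclusive(self):
        vec = zero_nutrient_vector()
        vec.update(energy=2000.0, protein=50.0)
        assert nutrient_bound_violations(vec, self._specs()) == []

    def test_maximum_exceeded(self):
        vec = zero_nutrient_vector()
        vec.update(energy=2700.0, protein=60.0)
        out = nutrient_bound_violations(vec, self._specs())
        assert [(v.nutrient, v.bound) for v in out] == [("energy", "max")]

    def test_zero_vector_violates_exactly_the_minima(self):
        out = nutrient_bound_violations(zero_nutrient_vector(), self._specs())
        assert sorted(v.nutrient for v in out) == ["energy", "protein"]


class TestFoodGroupBounds:
    GROUPS = {"steak": "red_meat", "carrot": "vegetables", "bread": "grains",
              "oil": "oil_fat"}
    ENERGY = {"steak": 2.5, "carrot": 0.3, "bread": 3.5, "oil": 8.8}

    def _bounds(self):
        return {
            "red_meat": FoodGroupBound("red_meat", 0.0, 28.0),
            "vegetables": FoodGroupBound("vegetables", 200.0, 600.0),
            "grains": FoodGroupBound("grains", 0.0, None,
                                     max_energy_share=0.60),
        }

    def test_red_meat_at_28_is_inclusive(self):
        diet = {"steak": 28.0, "carrot": 300.0, "bread": 50.0}
        assert food_group_violations(diet, self.GROUPS, self._bounds(),
                                     self.ENERGY) == []

    def test_vegetable_minimum(self):
        diet = {"carrot": 150.0, "bread": 30.0, "oil": 30.0}
        out = food_group_violations(diet, self.GROUPS, self._bounds(),
                                    self.ENERGY)
        assert [(v.group, v.bound) for v in out] == [("vegetables", "min")]

    def test_grains_energy_share(self):
        # bread at 61% of energy intake violates the 60% share bound
        diet = {"bread": 61.0, "oil": 3.5 * 39.0 / 8.8, "carrot": 250.0}
        energy = {"bread": 3.5, "oil": 8.8, "carrot": 0.0}
        out = food_group_violations(diet, self.GROUPS, self._bounds(), energy)
        assert [(v.group, v.bound) for v in out] == [
            ("grains", "max_energy_share")]

    def test_unmapped_food_rejected(self):
        with pytest.raises(KeyError):
            food_group_violations({"ufo": 1.0}, {}, self._bounds(), {})


class TestProteinMatch:
    def test_exact_match_is_empty(self):
        cur = {"C1": {"grains": 30.0, "dairy": 12.0}}
        assert protein_supply_match(cur, cur) == []

    def test_ninety_percent_shortfall(self):
        cur = {"C1": {"grains": 30.0}}
        got = {"C1": {"grains": 27.0}}
        out = protein_supply_match(got, cur)
        assert len(out) == 1
        assert out[0].shortfall_g_day == pytest.approx(3.0)

    def test_zero_production_full_shortfall(self):
        cur = {"C1": {"grains": 30.0, "dairy": 12.0}}
        out = protein_supply_match({}, cur)
        assert sorted((s.group, s.shortfall_g_day) for s in out) == [
            ("dairy", 12.0), ("grains", 30.0)]
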