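"""Technical conversion factors, waste pools, sludge and compost."""

import pytest

from circfood.instance import ResidualParams
from circfood.residuals import (
    byproducts_from_processing,
    compost_nutrients,
    sludge_fertilizer,
    waste_feed_allocation,
)

PARAMS = ResidualParams()


class TestByproducts:
    TCF = {"main_fraction": 0.75, "byproducts": {"bran": 0.22}}

    def test_zero_input(self):
        out = byproducts_from_processing(0.0, self.TCF)
        assert all(v == 0.0 for v in out.values())

    def test_fraction_arithmetic(self):
        out = byproducts_from_processing(100.0, self.TCF)
        assert out["main"] == pytest.approx(75.0)
        assert out["bran"] == pytest.approx(22.0)

    @pytest.mark.parametrize("mass", [1.0, 57.3, 1e6])
    def test_mass_out_never_exceeds_mass_in(self, mass):
        out = byproducts_from_processing(mass, self.TCF)
        assert sum(out.values()) <= mass + 1e-9

    def test_fractions_above_one_rejected(self):
        with pytest.raises(ValueError):
            byproducts_from_processing(
                1.0, {"main_fraction": 0.8, "byproducts": {"b": 0.3}})


class TestWasteAllocation:
    def test_thirty_five_percent_split(self):
        feed, compost = waste_feed_allocation(100.0, PARAMS)
        assert feed == pytest.approx(35.0)
        assert compost == pytest.approx(65.0)

    def test_zero_waste(self):
        assert waste_feed_allocation(0.0, PARAMS) == (0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            waste_feed_allocation(-1.0, PARAMS)


class TestSludge:
    def test_stated_fractions(self):
        out = sludge_fertilizer(100.0, PARAMS)
        assert out["usable_t"] == pytest.approx(36.0)
        assert out["n_t"] == pytest.approx(2.7)
        assert out["p_t"] == pytest.approx(0.432)

    def test_zero(self):
        out = sludge_fertilizer(0.0, PARAMS)
        assert all(v == 0.0 for v in out.values())

    def test_applied_convention(self):
        # when the input is already the applied (post-36%) amount, e.g. the
        # baseline's 3.2 Mt figure: 240 kt N and 38.4 kt P
        out = sludge_fertilizer(3.2e6, PARAMS, already_usable=True)
        assert out["n_t"] == pytest.approx(240e3)
        assert out["p_t"] == pytest.approx(38.4e3)


class TestCompost:
    def test_zero_waste(self):
        out = compost_nutrients(0.0, 0.0, PARAMS)
        assert out == {"n_t": 0.0, "p_t": 0.0}

    def test_gaseous_n_loss(self):
        params = ResidualParams(compost_n_loss_frac=0.05)
        out = compost_nutrients(10.0, 2.0, params)
        assert out["n_t"] == pytest.approx(9.5)

    def test_p_conserved_exactly(self):
        out = compost_nutrients(10.0, 2.0, PARAMS)
        assert out["p_t"] == 2.0
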