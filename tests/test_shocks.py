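"""Scenario-to-shock translation rules and their calibration anchors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epicge import (PandemicScenario, RegionAssumptions, ScenarioError,
                    ShockSet, annualize, build_shock_set, face_to_face_tax,
                    fiscal_stimulus, freight_advalorem, labor_shock,
                    logistics_shocks, oil_supply_shock, solve_equilibrium)
from epicge.shocks import APRIL, SEPTEMBER


class TestAnnualize:
    @pytest.mark.parametrize("days, want", [(10, 10 / 365), (0, 0.0), (365, 1.0)])
    def test_day_fractions(self, days, want):
        assert annualize(days) == pytest.approx(want)

    def test_negative_duration_rejected(self):
        with pytest.raises(ScenarioError):
            annualize(-1.0)


class TestLaborShock:
    def test_twelve_weeks_full_idleness_cuts_labor_23_percent(self):
        sc = PandemicScenario(regions={"x": RegionAssumptions(
            confinement_weeks=12, idle_fraction=1.0, telework_share=0.0)})
        m = labor_shock(sc, "x")
        assert 1.0 - m["unskilled"] == pytest.approx(12 / 52)
        assert 1.0 - m["unskilled"] == pytest.approx(0.23, abs=0.002)

    def test_eight_weeks_africa_cuts_15_percent(self):
        sc = PandemicScenario(regions={"x": RegionAssumptions(
            confinement_weeks=8, idle_fraction=1.0, telework_share=0.0)})
        m = labor_shock(sc, "x")
        assert 1.0 - m["unskilled"] == pytest.approx(8 / 52)
        assert 1.0 - m["unskilled"] == pytest.approx(0.15, abs=0.005)

    def test_telework_shields_one_third_of_skilled(self):
        sc = PandemicScenario(regions={"x": RegionAssumptions(
            confinement_weeks=12, telework_share=1 / 3)})
        m = labor_shock(sc, "x")
        assert 1.0 - m["skilled"] == pytest.approx((12 / 52) * (2 / 3))

    @given(st.floats(0.0, 52.0), st.floats(0.0, 52.0))
    @settings(max_examples=50, deadline=None)
    def test_more_confinement_weeks_never_raise_multipliers(self, w1, w2):
        lo, hi = sorted((w1, w2))
        m = [labor_shock(PandemicScenario(regions={"x": RegionAssumptions(
            confinement_weeks=w)}), "x") for w in (lo, hi)]
        assert m[1]["unskilled"] <= m[0]["unskilled"] + 1e-12
        assert m[1]["skilled"] <= m[0]["skilled"] + 1e-12


class TestFaceToFaceTax:
    def test_april_is_uniform_25_percent(self):
        assert face_to_face_tax(PandemicScenario(), "anywhere") == 0.25

    @pytest.mark.parametrize("intensity, want", [(0.0, 0.13), (1.0, 0.45),
                                                 (0.5, 0.29)])
    def test_september_interpolates_13_to_45(self, intensity, want):
        sc = PandemicScenario(template=SEPTEMBER, regions={
            "x": RegionAssumptions(distancing_intensity=intensity)})
        assert face_to_face_tax(sc, "x") == pytest.approx(want)

    def test_september_without_intensity_is_an_error(self):
        with pytest.raises(ScenarioError, match="intensity"):
            face_to_face_tax(PandemicScenario(template=SEPTEMBER), "x")


class TestLogisticsAndFreight:
    def test_default_wedges(self):
        loss, tfp = logistics_shocks(PandemicScenario())
        assert (loss, tfp) == (0.05, 0.95)

    def test_neutral_scenario_has_no_wedges(self):
        loss, tfp = logistics_shocks(PandemicScenario.neutral())
        assert (loss, tfp) == (0.0, 1.0)

    def test_iceberg_loss_accounting(self):
        loss, _ = logistics_shocks(PandemicScenario())
        assert 100.0 * (1.0 - loss) == pytest.approx(95.0)

    @pytest.mark.parametrize("days, rate, want",
                             [(0, 0.01, 0.0), (6, 0.005, 0.03), (4, 0.005, 0.02)])
    def test_freight_days_to_advalorem(self, days, rate, want):
        assert freight_advalorem(days, rate) == pytest.approx(want)


class TestStimulus:
    def test_flagged_region_gets_3_2_percent_of_gdp(self, world):
        transfers = fiscal_stimulus(world["scenario"], world["model"])
        model = world["model"]
        for i, rp in enumerate(model.regions):
            if "oecd_stimulus" in rp.region_tags:
                assert transfers[i] == pytest.approx(0.032 * rp.GDP0)
            else:
                assert transfers[i] == 0.0

    def test_us_style_override(self, world):
        sc = PandemicScenario(stimulus_share=0.11, regions=world["scenario"].regions)
        transfers = fiscal_stimulus(sc, world["model"])
        i = world["model"].region_index("oecd")
        assert transfers[i] == pytest.approx(0.11 * world["model"].regions[i].GDP0)


class TestOilShock:
    def test_zero_target_means_no_shift(self, world):
        assert oil_supply_shock(world["model"], (0.0, 0.0)) == 1.0

    def test_infeasible_target_reports_bracket_failure(self, world):
        with pytest.raises(ScenarioError):
            oil_supply_shock(world["model"], (-0.99, 0.0), max_shifter=1.5)

    def test_bisection_hits_crude_target_within_half_point(self, world, april,
                                                           base_eq):
        """The calibrated shifter moves the world energy price to -25% +- 0.5pp
        in the full scenario."""
        model = world["model"]
        energy = model.tag_mask("energy")
        pw = april["eq"].pw[energy]
        w = np.maximum(model.W0[energy], 1e-12)
        achieved = float(np.average(pw, weights=w)) - 1.0
        assert achieved == pytest.approx(-0.25, abs=0.005)


class TestBuildShockSet:
    def test_april_template_composition(self, world, april):
        shocks = april["shocks"]
        model = world["model"]
        f2f = model.tag_mask("face_to_face")
        assert np.allclose(shocks.shadow_tax[:, f2f], 0.25)
        mult = shocks.labor_multipliers()
        i_af = model.region_index("africa")
        for i in range(model.n_regions):
            want = 8 / 52 if i == i_af else 12 / 52
            assert mult[i, 0] == pytest.approx(1.0 - want)
            assert mult[i, 1] == pytest.approx(1.0 - want * (2 / 3))
        assert shocks.freight_margin == pytest.approx(0.03)
        perish = model.tag_mask("perishable")
        assert np.allclose(shocks.perish_loss[perish], 0.05)
        assert np.allclose(shocks.perish_loss[~perish], 0.0)

    def test_empty_scenario_gives_neutral_set_and_benchmark(self, world, base_eq):
        model = world["model"]
        shocks = build_shock_set(PandemicScenario.neutral(), model)
        assert shocks.is_neutral()
        eq = solve_equilibrium(model, shocks)
        np.testing.assert_allclose(eq.X, base_eq.X, rtol=1e-9)
        np.testing.assert_allclose(eq.pd, base_eq.pd, rtol=1e-9)

    def test_september_yields_distinct_regional_taxes(self, world):
        spec = world["spec"]
        sc = PandemicScenario(template=SEPTEMBER,
                              regions=dict(world["scenario"].regions))
        model = world["model"]
        shocks = build_shock_set(sc, model, calibrate_oil=False)
        f2f = model.tag_mask("face_to_face")
        rates = shocks.shadow_tax[:, f2f].ravel()
        assert len(set(np.round(rates, 6))) == model.n_regions
        assert np.all((rates >= 0.13) & (rates <= 0.45))

    def test_shadow_tax_demand_response_about_one_third(self, world):
        """A 25% wedge on face-to-face services cuts their consumption demand
        by 25-40% at unchanged income (ceteris paribus LES response)."""
        model = world["model"]
        f2f = model.tag_mask("face_to_face")
        for rp in model.regions:
            p0 = 1.0 + rp.t_com
            p1 = p0 * np.where(f2f, 1.25, 1.0)
            V1 = rp.Ctot0 - float(p1 @ rp.gamma)
            q1 = rp.gamma + rp.beta * V1 / p1
            drop = 1.0 - q1[f2f] / rp.q_cons0[f2f]
            assert np.all(drop > 0.25) and np.all(drop < 0.40)
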