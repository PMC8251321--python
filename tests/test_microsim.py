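"""Top-down link, household updates, poverty and diet accounting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from epicge import (LinkVector, MicrosimError, diet_shift, engel_food_share,
                    extract_link, household_price_index, poverty_headcount,
                    update_income)
from epicge.microsim import SECTOR_GROUPS, SKILLS

pytestmark = []


def tiny_survey(incomes, weights=None, region="africa", area=None,
                sectors=("grains", "services")):
    n = len(incomes)
    df = pd.DataFrame({
        "region": region,
        "area": area if area is not None else ["urban"] * n,
        "weight": weights if weights is not None else np.ones(n),
        "income0": incomes,
    })
    for k in SKILLS:
        for g in SECTOR_GROUPS:
            df[f"inc_{k}_{g}"] = 0.0
    df["inc_capital"] = 0.0
    df["inc_transfers"] = 0.0
    df["inc_unskilled_other"] = 1.0
    for j, s in enumerate(sectors):
        df[f"exp_{s}"] = 1.0 / len(sectors)
    return df


def zero_link(sectors=("grains", "services"), regions=("africa",)):
    return LinkVector.zero(list(regions), list(sectors))


class TestEngelCurve:
    def test_anchors_and_shape(self):
        line = 1.9
        poorest = line * np.exp(-1.5)
        richest = line * np.exp(5.5)
        assert engel_food_share(poorest, line) == pytest.approx(0.70, abs=0.01)
        assert engel_food_share(richest, line) == pytest.approx(0.15, abs=0.01)
        x = np.linspace(-1.5, 5.5, 200)
        shares = engel_food_share(line * np.exp(x), line)
        assert np.all(np.diff(shares) <= 1e-12)          # monotone decreasing
        assert np.all((shares >= 0.05) & (shares <= 0.85))

    def test_depends_only_on_income_relative_to_line(self):
        assert engel_food_share(3.8, 1.9) == engel_food_share(40.0, 20.0)

    def test_nonpositive_income_rejected(self):
        with pytest.raises(MicrosimError):
            engel_food_share(0.0, 1.9)


class TestUpdateIncome:
    def test_zero_link_leaves_income_unchanged(self):
        df = tiny_survey([2.0, 5.0, 9.0])
        np.testing.assert_allclose(update_income(df, zero_link()),
                                   df["income0"].to_numpy())

    def test_single_source_wage_and_employment_multiply(self):
        df = tiny_survey([10.0])
        link = zero_link()
        link.wage_change["unskilled"][:] = -0.10
        link.employment_change[("unskilled", "other")][:] = -0.20
        assert update_income(df, link)[0] == pytest.approx(10.0 * 0.9 * 0.8)

    def test_stochastic_mode_matches_binomial_mean(self):
        n = 10_000
        df = tiny_survey(np.full(n, 10.0))
        link = zero_link()
        link.wage_change["unskilled"][:] = -0.05
        link.employment_change[("unskilled", "other")][:] = -0.20
        y = update_income(df, link, mode="stochastic", seed=7)
        factor = y / 10.0
        want = 0.80 * 0.95
        se = 0.95 * np.sqrt(0.2 * 0.8 / n)
        assert abs(factor.mean() - want) < 3 * se
        assert set(np.round(factor, 6)) <= {0.0, np.round(0.95, 6)}

    def test_same_seed_reproduces_the_lottery(self):
        df = tiny_survey(np.full(500, 10.0))
        link = zero_link()
        link.employment_change[("unskilled", "other")][:] = -0.3
        a = update_income(df, link, mode="stochastic", seed=11)
        b = update_income(df, link, mode="stochastic", seed=11)
        np.testing.assert_array_equal(a, b)

    def test_unknown_mode_rejected(self):
        with pytest.raises(MicrosimError):
            update_income(tiny_survey([1.0]), zero_link(), mode="jackpot")


class TestPriceIndex:
    def test_unchanged_prices_give_zero(self):
        assert household_price_index(tiny_survey([2.0]), zero_link())[0] == 0.0

    def test_uniform_rise_passes_through(self):
        link = zero_link()
        link.price_change[:] = 0.10
        np.testing.assert_allclose(
            household_price_index(tiny_survey([2.0, 4.0]), link), 0.10)

    @pytest.mark.parametrize("food_share, want", [(0.7, 0.07), (0.15, 0.015)])
    def test_food_price_rise_weighted_by_engel_share(self, food_share, want):
        df = tiny_survey([2.0])
        df["exp_grains"] = food_share
        df["exp_services"] = 1.0 - food_share
        link = zero_link()
        link.price_change[:, 0] = 0.10        # food only
        assert household_price_index(df, link)[0] == pytest.approx(want)


class TestPovertyHeadcount:
    def test_no_poor_when_everyone_is_far_above_the_line(self):
        df = tiny_survey(np.full(10, 19.0))
        res = poverty_headcount(df, df["income0"].to_numpy())
        assert res.headcount_rate == 0.0
        assert res.poor_millions == 0.0

    def test_direct_count_five_households(self):
        df = tiny_survey([1.0, 1.5, 2.0, 2.5, 3.0])
        res = poverty_headcount(df, df["income0"].to_numpy(), 0.0, line=1.90)
        assert res.headcount_rate == pytest.approx(40.0)

    def test_lognormal_headcount_matches_analytic_cdf(self):
        """50,000 lognormal incomes: the weighted headcount equals the
        lognormal CDF at the line within 3 binomial standard errors."""
        n = 50_000
        mu, sigma = np.log(3.8), 1.0
        rng = np.random.default_rng(123)
        df = tiny_survey(rng.lognormal(mu, sigma, n))
        res = poverty_headcount(df, df["income0"].to_numpy(), 0.0, line=1.90)
        p = norm.cdf((np.log(1.90) - mu) / sigma)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(res.headcount_rate / 100.0 - p) < 3 * se

    def test_scale_equivariance_under_uniform_growth(self):
        rng = np.random.default_rng(5)
        df = tiny_survey(rng.lognormal(1.0, 0.8, 2_000))
        k = 1.23
        base = poverty_headcount(df, df["income0"].to_numpy(), 0.0, line=1.90 / k)
        grown = poverty_headcount(df, k * df["income0"].to_numpy(), 0.0, line=1.90)
        assert grown.headcount_rate == pytest.approx(base.headcount_rate)

    def test_raising_an_income_never_adds_poor(self):
        rng = np.random.default_rng(9)
        df = tiny_survey(rng.lognormal(0.8, 0.9, 500))
        y = df["income0"].to_numpy()
        before = poverty_headcount(df, y).poor_millions
        for i in (0, 100, 499):
            y2 = y.copy()
            y2[i] *= 1.5
            assert poverty_headcount(df, y2).poor_millions <= before

    def test_deflator_moves_real_income(self):
        df = tiny_survey([2.0])
        assert poverty_headcount(df, df["income0"].to_numpy(), 0.10).headcount_rate == 100.0
        assert poverty_headcount(df, df["income0"].to_numpy(), 0.0).headcount_rate == 0.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(MicrosimError):
            poverty_headcount(tiny_survey([1.0, 2.0]), np.array([1.0]))


class TestLinkAndAggregation:
    def test_identical_equilibria_give_zero_link(self, world, base_eq):
        link = extract_link(base_eq, base_eq)
        for v in link.wage_change.values():
            np.testing.assert_allclose(v, 0.0, atol=1e-12)
        np.testing.assert_allclose(link.price_change, 0.0, atol=1e-12)
        np.testing.assert_allclose(link.transfer_change, 0.0, atol=1e-12)

    def test_wage_entry_is_the_direct_ratio(self, world, base_eq, april):
        link = extract_link(base_eq, april["eq"])
        i = world["model"].region_index("africa")
        want = april["eq"].wu[i] / base_eq.wu[i] - 1.0
        assert link.wage_change["unskilled"][i] == pytest.approx(want)

    def test_stimulus_only_run_moves_transfers_not_wages(self, world, base_eq):
        from epicge import ShockSet, solve_equilibrium
        model = world["model"]
        shocks = ShockSet.neutral(model)
        i = model.region_index("oecd")
        shocks.stimulus[i] = 0.032 * model.regions[i].GDP0
        eq = solve_equilibrium(model, shocks)
        link = extract_link(base_eq, eq)
        assert link.transfer_change[i] > 0.01
        assert abs(link.wage_change["unskilled"][i]) < 0.02

    def test_uniform_link_aggregates_to_representative_household(self, world,
                                                                 base_eq):
        """Under a purely uniform income change the person-weighted survey
        income change equals the representative household's change to 1e-9."""
        model = world["model"]
        survey = world["survey"]
        link = LinkVector.zero([rp.region_id for rp in model.regions],
                               model.sectors)
        for k in SKILLS:
            link.wage_change[k][:] = -0.07
        link.capital_change[:] = -0.07
        link.transfer_change[:] = -0.07
        y1 = update_income(survey, link)
        np.testing.assert_allclose(y1, 0.93 * survey["income0"].to_numpy(),
                                   rtol=1e-9)

    def test_full_link_aggregation_consistent_within_tolerance(self, world,
                                                               base_eq, april):
        """Survey-aggregated income changes track the representative
        household's nominal income change within the reconciliation tolerance."""
        model = world["model"]
        survey = world["survey"]
        link = extract_link(base_eq, april["eq"])
        y0 = survey["income0"].to_numpy()
        y1 = update_income(survey, link)
        w = survey["weight"].to_numpy()
        for i, rp in enumerate(model.regions):
            m = (survey["region"] == rp.region_id).to_numpy()
            survey_chg = float((w[m] * y1[m]).sum() / (w[m] * y0[m]).sum()) - 1.0
            rep_chg = (april["eq"].FY[i] + april["eq"].TR[i]) / (rp.FY0 + rp.TR0) - 1.0
            assert survey_chg == pytest.approx(rep_chg, abs=0.02)


class TestDietShift:
    def test_no_change_between_identical_equilibria(self, world, base_eq):
        df = diet_shift(base_eq, base_eq)
        np.testing.assert_allclose(df["pct_change"], 0.0, atol=1e-9)

    def test_two_group_toy_returns_exact_numbers(self, world, base_eq):
        import copy
        sim = copy.copy(base_eq)
        sim.quants = dict(base_eq.quants)
        model = world["model"]
        st_mask = model.tag_mask("staple")
        fv_mask = np.array([s == "fruitveg" for s in model.sectors])
        q = base_eq.q_cons.copy()
        q[:, st_mask] *= 1.02
        q[:, fv_mask] *= 0.94
        sim.quants["q_cons"] = q
        df = diet_shift(base_eq, sim,
                        grouping={"staples": ("grains",),
                                  "fv": ("fruitveg",)}).set_index(["group", "region"])
        assert df.loc[("staples", "world"), "pct_change"] == pytest.approx(2.0)
        assert df.loc[("fv", "world"), "pct_change"] == pytest.approx(-6.0)

    def test_empty_group_rejected(self, world, base_eq):
        with pytest.raises(MicrosimError):
            diet_shift(base_eq, base_eq, grouping={"nope": ("unobtainium",)})
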