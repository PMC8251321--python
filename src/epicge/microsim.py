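"""Top-down macro-micro link: from equilibrium changes to household outcomes.

The link is one-way: the solved equilibrium pair (base, shocked) is condensed
into a vector of relative changes -- factor prices, employment by skill and
sector group, consumer prices, transfers -- which is then applied to each
survey household according to its income-source and expenditure composition.
Households differ in how the same macro shock reaches them: workers supplying
unskilled labor in locked-down sectors lose more income, and each household
faces its own cost-of-living change through its own budget shares.

Surveys are plain DataFrames.  Column schema:

======================  =====================================================
``region``              region id matching the model
``area``                ``rural`` or ``urban``
``weight``              persons represented (poverty counts are persons)
``income0``             base income per capita, PPP$ per person per day
``inc_<skill>_<group>`` income share from wages of *skill* in sector *group*
                        (groups: agrifood, face_to_face, transport, other)
``inc_capital``         income share from capital
``inc_transfers``       income share from public transfers
``exp_<sector>``        expenditure share on each model commodity
======================  =====================================================

Income shares and expenditure shares each sum to one per household.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibrium import Equilibrium, _sector_groups

INTL_POVERTY_LINE = 1.90      # PPP$ per person per day

SECTOR_GROUPS = ("agrifood", "face_to_face", "transport", "other")
SKILLS = ("unskilled", "skilled")

#: default cubic for the food expenditure share in x = ln(income / national
#: poverty line): anchored at 0.70 (x = -1.5) and 0.15 (x = +5.5) with zero
#: slope at both anchors, hence monotone decreasing between them.
ENGEL_COEFFS = (0.63505831, -0.07937318, -0.01924198, 0.00320700)
ENGEL_CLIP = (0.05, 0.85)


class MicrosimError(ValueError):
    pass


def engel_food_share(income, national_poverty_line=INTL_POVERTY_LINE,
                     coeffs=ENGEL_COEFFS):
    """Food expenditure share from a cubic in log income relative to the
    national poverty line; clipped to a plausible band.  Vectorized."""
    income = np.asarray(income, dtype=float)
    if np.any(income <= 0):
        raise MicrosimError("income must be positive")
    x = np.log(income / national_poverty_line)
    c0, c1, c2, c3 = coeffs
    share = c0 + c1 * x + c2 * x**2 + c3 * x**3
    out = np.clip(share, *ENGEL_CLIP)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# link vector
# ---------------------------------------------------------------------------

@dataclass
class LinkVector:
    """Relative changes passed from the equilibrium pair to the survey."""

    regions: list                      # region ids, defining the row order
    sectors: list
    wage_change: dict                  # skill -> (R,) relative change
    capital_change: np.ndarray         # (R,)
    employment_change: dict            # (skill, group) -> (R,)
    price_change: np.ndarray           # (R, S) consumer price relative change
    transfer_change: np.ndarray        # (R,) relative change of transfers

    def __post_init__(self) -> None:
        for d in (*self.wage_change.values(), self.capital_change,
                  *self.employment_change.values(), self.transfer_change):
            if np.any(np.asarray(d) <= -1.0):
                raise MicrosimError("relative changes must exceed -1")

    def region_row(self, region_id: str) -> int:
        return self.regions.index(region_id)

    @classmethod
    def zero(cls, regions, sectors) -> "LinkVector":
        R, S = len(regions), len(sectors)
        z = np.zeros(R)
        return cls(
            regions=list(regions), sectors=list(sectors),
            wage_change={k: z.copy() for k in SKILLS},
            capital_change=z.copy(),
            employment_change={(k, g): z.copy() for k in SKILLS for g in SECTOR_GROUPS},
            price_change=np.zeros((R, S)),
            transfer_change=z.copy(),
        )


def extract_link(base: Equilibrium, sim: Equilibrium) -> LinkVector:
    """Condense two equilibria into the microsimulation's link vector."""
    m = base.model
    regions = [rp.region_id for rp in m.regions]
    emp_b = base.employment_by_group()
    emp_s = sim.employment_by_group()
    emp = {}
    for key in emp_b:
        with np.errstate(invalid="ignore", divide="ignore"):
            emp[key] = np.where(emp_b[key] > 0, emp_s[key] / emp_b[key] - 1.0, 0.0)
    return LinkVector(
        regions=regions, sectors=list(m.sectors),
        wage_change={
            "unskilled": sim.wu / base.wu - 1.0,
            "skilled": sim.ws / base.ws - 1.0,
        },
        capital_change=sim.cap_income / base.cap_income - 1.0,
        employment_change=emp,
        price_change=sim.p_cons / base.p_cons - 1.0,
        transfer_change=sim.TR / base.TR - 1.0,
    )


# ---------------------------------------------------------------------------
# household-level updates
# ---------------------------------------------------------------------------

def _source_columns(survey: pd.DataFrame) -> list:
    cols = [c for c in survey.columns if c.startswith("inc_")]
    expected = {f"inc_{k}_{g}" for k in SKILLS for g in SECTOR_GROUPS}
    expected |= {"inc_capital", "inc_transfers"}
    unknown = set(cols) - expected
    if unknown:
        raise MicrosimError(f"unknown income-source columns: {sorted(unknown)}")
    return cols


def update_income(
    survey: pd.DataFrame,
    link: LinkVector,
    mode: str = "proportional",
    seed: int | None = None,
) -> np.ndarray:
    """New nominal income per capita for every household.

    ``proportional`` (deterministic): each source is scaled by
    ``(1 + dwage)(1 + demployment)``.  ``stochastic``: an employment decline
    becomes a Bernoulli job-loss lottery (probability = the decline) that
    zeroes the source; reproducible through ``seed``.
    """
    if mode not in ("proportional", "stochastic"):
        raise MicrosimError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    cols = _source_columns(survey)
    rows = np.array([link.region_row(r) for r in survey["region"]])
    n = len(survey)
    factor_total = np.zeros(n)
    for col in cols:
        share = survey[col].to_numpy(dtype=float)
        if col == "inc_capital":
            price = link.capital_change[rows]
            emp = np.zeros(n)
        elif col == "inc_transfers":
            price = link.transfer_change[rows]
            emp = np.zeros(n)
        else:
            _, skill, group = col.split("_", 2)
            price = link.wage_change[skill][rows]
            emp = link.employment_change[(skill, group)][rows]
        if mode == "stochastic" and col not in ("inc_capital", "inc_transfers"):
            decline = np.clip(-emp, 0.0, 1.0)
            keep = rng.random(n) >= decline
            gain = np.clip(emp, 0.0, None)     # expansions stay proportional
            emp_factor = keep * (1.0 + gain)
        else:
            emp_factor = 1.0 + emp
        factor_total += share * (1.0 + price) * emp_factor
    return survey["income0"].to_numpy(dtype=float) * factor_total


def household_price_index(survey: pd.DataFrame, link: LinkVector) -> np.ndarray:
    """Laspeyres cost-of-living relative change per household:
    sum of expenditure shares times commodity price changes."""
    rows = np.array([link.region_row(r) for r in survey["region"]])
    out = np.zeros(len(survey))
    for j, s in enumerate(link.sectors):
        col = f"exp_{s}"
        if col not in survey.columns:
            raise MicrosimError(f"missing expenditure column {col}")
        out += survey[col].to_numpy(dtype=float) * link.price_change[rows, j]
    return out


# ---------------------------------------------------------------------------
# poverty accounting
# ---------------------------------------------------------------------------

@dataclass
class PovertyResult:
    """Extreme-poverty headcount against a real PPP$/day line."""

    line: float
    headcount_rate: float              # % of persons
    poor_millions: float
    by_region: pd.DataFrame            # region x area table of rates and counts
    total_persons_millions: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.headcount_rate <= 100.0):
            raise MicrosimError("headcount rate out of [0, 100]")


def poverty_headcount(
    survey: pd.DataFrame,
    incomes: np.ndarray,
    deflators: np.ndarray | float = 0.0,
    line: float = INTL_POVERTY_LINE,
) -> PovertyResult:
    """Weighted headcount of persons whose real income falls below the line.

    A household is poor iff ``income / (1 + deflator) < line``; the deflator
    is its idiosyncratic cost-of-living change since base.  Weights are
    persons.
    """
    incomes = np.asarray(incomes, dtype=float)
    deflators = np.broadcast_to(np.asarray(deflators, dtype=float), incomes.shape)
    if len(incomes) != len(survey):
        raise MicrosimError("incomes misaligned with the survey")
    w = survey["weight"].to_numpy(dtype=float)
    poor = (incomes / (1.0 + deflators)) < line
    total = w.sum()
    rate = 100.0 * float(w[poor].sum()) / total
    df = survey[["region", "area"]].copy()
    df["weight"] = w
    df["poor_w"] = w * poor
    by = (
        df.groupby(["region", "area"], sort=True)[["weight", "poor_w"]]
        .sum()
        .assign(rate=lambda t: 100.0 * t["poor_w"] / t["weight"])
        .rename(columns={"poor_w": "poor_persons"})
        .reset_index()
    )
    by["poor_millions"] = by["poor_persons"] / 1e6
    return PovertyResult(
        line=line, headcount_rate=rate,
        poor_millions=float(w[poor].sum()) / 1e6,
        by_region=by[["region", "area", "weight", "poor_millions", "rate"]],
        total_persons_millions=total / 1e6,
    )


# ---------------------------------------------------------------------------
# diet outcomes
# ---------------------------------------------------------------------------

DEFAULT_FOOD_GROUPS = {
    "staple grains": ("staple",),
    "fruits & vegetables": ("fruitveg",),
    "meat & dairy": ("meatdairy",),
}


def diet_shift(base: Equilibrium, sim: Equilibrium, grouping: dict | None = None
               ) -> pd.DataFrame:
    """Percent change of food consumption volumes per food group.

    Regional volume changes are aggregated with base-value consumption
    weights; volumes are the households' consumed quantities.  ``grouping``
    maps a group label to the sector names (or name fragments) it covers.
    """
    m = base.model
    grouping = grouping or _default_grouping(m)
    q0, q1 = base.q_cons, sim.q_cons
    v0 = base.p_cons * q0                       # base value weights
    rows = []
    for group, members in grouping.items():
        mask = np.array([s in members for s in m.sectors])
        if not mask.any():
            raise MicrosimError(f"empty food group {group!r}")
        w = v0[:, mask]
        if w.sum() <= 0:
            raise MicrosimError(f"no base consumption in group {group!r}")
        change = q1[:, mask] / q0[:, mask] - 1.0
        world = float(np.average(change, weights=w))
        rows.append({"group": group, "pct_change": 100.0 * world})
        for r, rp in enumerate(m.regions):
            rows.append({
                "group": group, "region": rp.region_id,
                "pct_change": 100.0 * float(np.average(change[r], weights=w[r])),
            })
    df = pd.DataFrame(rows)
    df["region"] = df.get("region", pd.Series(dtype=object))
    df["region"] = df["region"].fillna("world")
    return df


def _default_grouping(model) -> dict:
    groups: dict = {}
    staple = [s for s in model.sectors
              if "staple" in model.regions[0].tags.get(s, frozenset())]
    perish = [s for s in model.sectors
              if "perishable" in model.regions[0].tags.get(s, frozenset())]
    fruit = [s for s in perish if "fruit" in s]
    meat = [s for s in perish if s not in fruit]
    if staple:
        groups["staple grains"] = tuple(staple)
    if fruit:
        groups["fruits & vegetables"] = tuple(fruit)
    if meat:
        groups["meat & dairy"] = tuple(meat)
    return groups
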