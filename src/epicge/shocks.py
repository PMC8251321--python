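"""Translate pandemic scenario assumptions into model-space shocks.

The model runs on an annual time step, so every disruption is annualized:
a disruption lasting d days counts as d/365 of the year (confinement weeks
as weeks/52).  The channels covered are:

* labor supply: health-related losses plus confinement-induced idleness, with
  a telework discount for skilled workers and an essential-sector exemption;
* a "shadow tax" on face-to-face services (final and intermediate use),
  a fear/lockdown wedge whose proceeds are destroyed, not collected;
* logistics: extra post-harvest losses on perishables and a transport
  productivity decline;
* world markets: trade-delay ad-valorem freight margins and an oil supply
  expansion targeted at a world energy price decline;
* fiscal stimulus transfers in high-income regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .calibrate import CalibratedModel

log = logging.getLogger(__name__)

WEEKS_PER_YEAR = 52.0
DAYS_PER_YEAR = 365.0

APRIL, SEPTEMBER = "april2020", "september2020"
SEPT_TAX_RANGE = (0.13, 0.45)


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class RegionAssumptions:
    """Per-region epidemiological and confinement inputs (plain scenario data)."""

    health_labor_loss: float = 0.0    # mortality+morbidity fraction of workforce-year
    confinement_weeks: float = 12.0
    idle_fraction: float = 1.0        # share of affected workforce idled while confined
    telework_share: float = 1.0 / 3.0  # skilled workers able to work remotely
    distancing_intensity: float = 0.5  # in [0,1]; scales the September shadow tax

    def __post_init__(self) -> None:
        if not (0.0 <= self.confinement_weeks <= WEEKS_PER_YEAR):
            raise ScenarioError(f"confinement weeks out of [0, 52]: {self.confinement_weeks}")
        for name in ("health_labor_loss", "idle_fraction", "telework_share",
                     "distancing_intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ScenarioError(f"{name} out of [0, 1]: {v}")


@dataclass(frozen=True)
class PandemicScenario:
    """Scenario assumptions; defaults reproduce the April-2020 template."""

    template: str = APRIL
    regions: dict = field(default_factory=dict)   # region_id -> RegionAssumptions
    shadow_tax_rate: float = 0.25                 # uniform April wedge
    shadow_tax_range: tuple = SEPT_TAX_RANGE      # September interpolation range
    postharvest_points: float = 0.05              # added loss on perishables
    transport_tfp_change: float = -0.05
    freight_delay_days: float = 6.0
    freight_per_day_rate: float = 0.005           # ad-valorem per day of delay
    oil_price_target_crude: float = -0.25
    oil_price_target_refined: float = -0.17
    stimulus_share: float = 0.032                 # of base GDP, OECD-flagged regions

    def __post_init__(self) -> None:
        if self.shadow_tax_rate < 0:
            raise ScenarioError("shadow tax must be nonnegative")
        if self.template not in (APRIL, SEPTEMBER, "neutral"):
            raise ScenarioError(f"unknown template {self.template!r}")

    def assumptions(self, region_id: str) -> RegionAssumptions:
        if region_id in self.regions:
            return self.regions[region_id]
        if self.template == "neutral":
            return RegionAssumptions(confinement_weeks=0.0)
        return RegionAssumptions()

    @classmethod
    def neutral(cls) -> "PandemicScenario":
        """An all-quiet scenario: every derived shock is neutral."""
        return cls(
            template="neutral", regions={},
            shadow_tax_rate=0.0, postharvest_points=0.0, transport_tfp_change=0.0,
            freight_delay_days=0.0, freight_per_day_rate=0.0,
            oil_price_target_crude=0.0, oil_price_target_refined=0.0,
            stimulus_share=0.0,
        )


@dataclass
class ShockSet:
    """The full vector of model-space shocks for one scenario.

    Labor reductions are stored before the essential-sector exemption;
    the equilibrium solver weights the distancing part by each skill's base
    employment share in exposed (non-essential) sectors.
    """

    labor_red_health: np.ndarray      # (R,)
    labor_red_dist: np.ndarray        # (R, 2) [unskilled, skilled] distancing cut
    sector_exposure: np.ndarray       # (S,) 1 = subject to the distancing shock
    shadow_tax: np.ndarray            # (R, S) wedge on face-to-face use
    perish_loss: np.ndarray           # (S,) extra post-harvest loss
    tfp_mult: np.ndarray              # (R, S) productivity multipliers
    freight_margin: float = 0.0       # ad-valorem on international trade
    stimulus: np.ndarray | None = None  # (R,) transfer, model money units
    savings_rule_active: bool = True

    def __post_init__(self) -> None:
        if self.stimulus is None:
            self.stimulus = np.zeros(self.labor_red_health.shape[0])
        m = self.labor_multipliers()
        if np.any(m < 0.0) or np.any(m > 1.0):
            raise ScenarioError("labor multipliers must lie in [0, 1]")
        if np.any(self.shadow_tax < 0) or np.any(self.perish_loss < 0):
            raise ScenarioError("wedges must be nonnegative")

    def labor_multipliers(self) -> np.ndarray:
        """Raw (R, 2) endowment multipliers before the essential exemption."""
        red = self.labor_red_health[:, None] + self.labor_red_dist
        return np.clip(1.0 - red, 0.0, 1.0)

    @classmethod
    def neutral(cls, model: CalibratedModel) -> "ShockSet":
        R, S = model.n_regions, model.n_sectors
        return cls(
            labor_red_health=np.zeros(R), labor_red_dist=np.zeros((R, 2)),
            sector_exposure=np.zeros(S), shadow_tax=np.zeros((R, S)),
            perish_loss=np.zeros(S), tfp_mult=np.ones((R, S)),
            freight_margin=0.0, stimulus=np.zeros(R),
        )

    def is_neutral(self) -> bool:
        return (
            not np.any(self.labor_red_health) and not np.any(self.labor_red_dist)
            and not np.any(self.shadow_tax) and not np.any(self.perish_loss)
            and np.allclose(self.tfp_mult, 1.0) and self.freight_margin == 0.0
            and not np.any(self.stimulus)
        )

    def scaled(self, alpha: float) -> "ShockSet":
        """Linearly scale every shock toward neutral (alpha=0) or full (alpha=1)."""
        return replace(
            self,
            labor_red_health=alpha * self.labor_red_health,
            labor_red_dist=alpha * self.labor_red_dist,
            shadow_tax=alpha * self.shadow_tax,
            perish_loss=alpha * self.perish_loss,
            tfp_mult=1.0 + alpha * (self.tfp_mult - 1.0),
            freight_margin=alpha * self.freight_margin,
            stimulus=alpha * self.stimulus,
        )

    #: channel names accepted by :meth:`without`
    CHANNELS = ("labor", "shadow_tax", "logistics", "world_markets", "stimulus",
                "savings")

    def without(self, channel: str) -> "ShockSet":
        """Delete one shock channel (for one-at-a-time decomposition)."""
        if channel == "labor":
            return replace(self, labor_red_health=np.zeros_like(self.labor_red_health),
                           labor_red_dist=np.zeros_like(self.labor_red_dist))
        if channel == "shadow_tax":
            return replace(self, shadow_tax=np.zeros_like(self.shadow_tax))
        if channel == "logistics":
            return replace(self, perish_loss=np.zeros_like(self.perish_loss),
                           tfp_mult=np.where(self.tfp_mult < 1.0, 1.0, self.tfp_mult))
        if channel == "world_markets":
            return replace(self, freight_margin=0.0,
                           tfp_mult=np.where(self.tfp_mult > 1.0, 1.0, self.tfp_mult))
        if channel == "stimulus":
            return replace(self, stimulus=np.zeros_like(self.stimulus))
        if channel == "savings":
            return replace(self, savings_rule_active=False)
        raise ScenarioError(f"unknown channel {channel!r}")


# ---------------------------------------------------------------------------
# elementary conversion rules
# ---------------------------------------------------------------------------

def annualize(duration: float, period: float = DAYS_PER_YEAR) -> float:
    """Fraction of the year a disruption of ``duration`` covers (10 days -> 10/365)."""
    if duration < 0:
        raise ScenarioError(f"negative duration {duration}")
    if duration > period:
        raise ScenarioError(f"duration {duration} exceeds period {period}")
    return duration / period


def labor_shock(scenario: PandemicScenario, region_id: str) -> dict:
    """Raw labor-supply multipliers {unskilled, skilled} for one region.

    Unskilled reduction = health loss + idle_fraction * weeks/52; skilled
    workers recover a telework share of the distancing loss.  12 weeks at
    full idleness gives a 23% cut, 8 weeks gives 15%.
    """
    a = scenario.assumptions(region_id)
    dist = a.idle_fraction * annualize(a.confinement_weeks, WEEKS_PER_YEAR)
    red_u = a.health_labor_loss + dist
    red_s = a.health_labor_loss + dist * (1.0 - a.telework_share)
    if red_u > 1.0 or red_s > 1.0:
        log.warning("labor reduction above 100%% in %s; clipping", region_id)
    return {
        "unskilled": max(0.0, 1.0 - min(red_u, 1.0)),
        "skilled": max(0.0, 1.0 - min(red_s, 1.0)),
    }


def face_to_face_tax(scenario: PandemicScenario, region_id: str) -> float:
    """Shadow-tax rate on face-to-face services for one region.

    April template: uniform rate (default 25%).  September template: linear in
    the region's distancing intensity over the configured range (13%--45%).
    """
    if scenario.template == SEPTEMBER:
        a = scenario.regions.get(region_id)
        if a is None:
            raise ScenarioError(
                f"september template needs a distancing intensity for {region_id!r}"
            )
        lo, hi = scenario.shadow_tax_range
        return lo + (hi - lo) * a.distancing_intensity
    return scenario.shadow_tax_rate


def logistics_shocks(scenario: PandemicScenario) -> tuple:
    """(post-harvest loss wedge on perishables, transport TFP multiplier)."""
    return scenario.postharvest_points, 1.0 + scenario.transport_tfp_change


def freight_advalorem(delay_days: float, per_day_rate: float) -> float:
    """Trade-delay cost as an ad-valorem margin: days lost x per-day rate."""
    if delay_days < 0 or per_day_rate < 0:
        raise ScenarioError("freight inputs must be nonnegative")
    return delay_days * per_day_rate


def fiscal_stimulus(scenario: PandemicScenario, model: CalibratedModel) -> np.ndarray:
    """Stimulus transfer per region: share of base GDP for OECD-flagged regions."""
    out = np.zeros(model.n_regions)
    for i, rp in enumerate(model.regions):
        if "oecd_stimulus" in rp.region_tags:
            out[i] = scenario.stimulus_share * rp.GDP0
    return out


def oil_supply_shock(
    model: CalibratedModel,
    targets: tuple,
    base_shocks: "ShockSet | None" = None,
    closure=None,
    tol_pp: float = 0.005,
    max_shifter: float = 3.0,
) -> float:
    """Energy-sector supply (TFP) shifter hitting a world energy price target.

    Bisects the shifter until the solved scenario's world real energy price
    change is within ``tol_pp`` (0.5 pp) of the crude-oil target.  With a
    single aggregate energy sector the crude target is the binding one.
    """
    from .equilibrium import solve_equilibrium  # deferred: avoids an import cycle

    crude = float(targets[0])
    if crude == 0.0:
        return 1.0
    if crude > 0.0 or crude <= -1.0:
        raise ScenarioError(f"energy price target out of range: {crude}")
    energy = model.tag_mask("energy")
    if not energy.any():
        raise ScenarioError("no energy sectors tagged")
    shocks = base_shocks if base_shocks is not None else ShockSet.neutral(model)
    weights = np.maximum(model.W0[energy], 1e-12)

    def price_change(shifter: float) -> float:
        trial = replace(shocks, tfp_mult=shocks.tfp_mult.copy())
        trial.tfp_mult[:, energy] = shocks.tfp_mult[:, energy] * shifter
        eq = solve_equilibrium(model, trial, closure)
        pw = eq.pw[energy]
        return float(np.average(pw, weights=weights) - 1.0)

    lo, f_lo = 1.0, price_change(1.0)
    if f_lo <= crude:
        return 1.0  # the demand collapse alone already overshoots the target
    hi = 1.2
    f_hi = price_change(hi)
    while f_hi > crude:
        if hi >= max_shifter:
            raise ScenarioError(
                f"cannot bracket energy price target {crude:+.0%} "
                f"(reached {f_hi:+.1%} at shifter {hi:g})"
            )
        lo, f_lo = hi, f_hi
        hi = min(max_shifter, hi * 1.5)
        f_hi = price_change(hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f_mid = price_change(mid)
        if abs(f_mid - crude) <= tol_pp:
            return mid
        if f_mid > crude:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_shock_set(
    scenario: PandemicScenario,
    model: CalibratedModel,
    closure=None,
    calibrate_oil: bool = True,
) -> ShockSet:
    """Compose every channel into the full ShockSet for a scenario.

    The essential agri-food exemption enters as a per-sector exposure flag;
    the oil shifter is found last, by bisection against the solved scenario,
    unless ``calibrate_oil`` is False (then the energy supply is unshifted).
    """
    R, S = model.n_regions, model.n_sectors
    f2f = model.tag_mask("face_to_face")
    perish = model.tag_mask("perishable")
    transport = model.tag_mask("transport")
    exposure = (~model.tag_mask("agrifood")).astype(float)

    health = np.zeros(R)
    dist = np.zeros((R, 2))
    tax = np.zeros((R, S))
    for i, rp in enumerate(model.regions):
        a = scenario.assumptions(rp.region_id)
        m = labor_shock(scenario, rp.region_id)
        health[i] = a.health_labor_loss
        dist[i, 0] = 1.0 - m["unskilled"] - a.health_labor_loss
        dist[i, 1] = 1.0 - m["skilled"] - a.health_labor_loss
        if scenario.template != "neutral":
            tax[i, f2f] = face_to_face_tax(scenario, rp.region_id)

    loss_pts, tfp_transport = logistics_shocks(scenario)
    perish_loss = np.where(perish, loss_pts, 0.0)
    tfp = np.ones((R, S))
    tfp[:, transport] = tfp_transport

    shocks = ShockSet(
        labor_red_health=health, labor_red_dist=dist, sector_exposure=exposure,
        shadow_tax=tax, perish_loss=perish_loss, tfp_mult=tfp,
        freight_margin=freight_advalorem(scenario.freight_delay_days,
                                         scenario.freight_per_day_rate),
        stimulus=fiscal_stimulus(scenario, model),
    )
    if calibrate_oil and scenario.oil_price_target_crude != 0.0:
        shifter = oil_supply_shock(
            model,
            (scenario.oil_price_target_crude, scenario.oil_price_target_refined),
            base_shocks=shocks, closure=closure,
        )
        energy = model.tag_mask("energy")
        tfp = shocks.tfp_mult.copy()
        tfp[:, energy] *= shifter
        shocks = replace(shocks, tfp_mult=tfp)
    return shocks
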