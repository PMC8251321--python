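"""Benchmark calibration: turn balanced SAMs into a solvable CGE parameter set.

Calibration follows standard CGE practice: with all base prices normalised to
one, base quantities equal SAM values, and every share/shift parameter is
chosen so that the benchmark equilibrium exactly replicates the SAM.  The
functional forms are the smallest set delivering the mechanisms the scenario
machinery needs:

* Leontief intermediate demand;
* value added produced by a CES aggregate of skilled and unskilled labor,
  with capital services tied in fixed proportion to labor use and earning a
  calibrated proportional quasi-rent (the within-year capital--labor
  utilization ratio is fixed, so capital income moves with activity);
* Armington CES between the domestic variety and a pooled import, with a
  world CES pool over regional varieties for each commodity;
* LES (Stone--Geary) household demand, so budget shares shift toward
  subsistence-heavy staples endogenously when income falls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .sam import CAP, SAM, SAMError, SLAB, ULAB, balance_check


class CalibrationError(ValueError):
    """Raised when a SAM cannot support the model's functional forms."""


@dataclass(frozen=True)
class ElasticityConfig:
    """Behavioural elasticities and LES curvature (config, not estimates).

    ``subsistence_shares`` maps a sector tag (or sector name, which takes
    precedence) to the fraction of base consumption that is subsistence in the
    LES.  Negative values mark luxuries (income elasticity above one).  The
    face-to-face entry is overridden so the implied own-price elasticity of
    demand for high-contact services equals ``f2f_demand_elasticity``.
    """

    sigma_labor: float = 1.5          # skilled/unskilled substitution
    sigma_armington: float = 3.0      # domestic vs imported variety
    sigma_world: float = 5.0          # across export source regions
    f2f_demand_elasticity: float = 1.8  # magnitude of own-price elasticity
    subsistence_shares: dict = field(
        default_factory=lambda: {
            "staple": 0.70,
            "fruitveg": 0.10,
            "meatdairy": 0.00,
            "face_to_face": -0.80,   # placeholder; recalibrated from elasticity
            "transport": 0.00,
            "energy": 0.30,
            "default": -0.10,
        }
    )

    def __post_init__(self) -> None:
        for name, v in (
            ("sigma_labor", self.sigma_labor),
            ("sigma_armington", self.sigma_armington),
            ("sigma_world", self.sigma_world),
            ("f2f_demand_elasticity", self.f2f_demand_elasticity),
        ):
            if v <= 0:
                raise CalibrationError(f"{name} must be > 0, got {v}")


@dataclass
class RegionParams:
    """Calibrated parameters and base values for one region (arrays over sectors)."""

    region_id: str
    sectors: list
    tags: dict                      # sector -> frozenset of tags
    region_tags: frozenset          # e.g. {"developing", "africa", "oecd_stimulus"}
    # technology
    a: np.ndarray                   # (S, S) intermediate coeffs, a[t, s] per unit of s
    labor_coef: np.ndarray          # (S,) labor-aggregate units per unit of output
    du: np.ndarray                  # (S,) CES share of unskilled in the labor nest
    ds: np.ndarray                  # (S,) CES share of skilled
    mu: np.ndarray                  # (S,) capital quasi-rent per unit of labor cost
    # trade
    X0: np.ndarray
    E0: np.ndarray
    M0: np.ndarray
    D0: np.ndarray
    dd: np.ndarray                  # Armington share of domestic variety
    dm: np.ndarray                  # Armington share of imports
    # fiscal
    t_com: np.ndarray               # (S,) net commodity tax rate on absorption
    theta: float                    # direct tax rate on factor income
    TR0: float                      # base government -> household transfer
    # demand
    gamma: np.ndarray               # (S,) LES subsistence quantities
    beta: np.ndarray                # (S,) LES marginal budget shares (sum 1)
    q_cons0: np.ndarray             # (S,) base consumed quantities (basic prices)
    C0: np.ndarray                  # (S,) base consumption values (purchaser)
    Ctot0: float
    g0: np.ndarray                  # (S,) real government consumption
    beta_inv: np.ndarray            # (S,) investment value shares
    I0: np.ndarray
    # endowments and balances
    LU0: float
    LS0: float
    WU0: np.ndarray                 # (S,) base unskilled wage bills
    WS0: np.ndarray
    K0: np.ndarray
    FY0: float                      # base factor income
    disp0: float                    # base disposable income
    S_h0: float
    S_g0: float
    F0: float                       # foreign savings into the region's pool
    GDP0: float                     # nominal base GDP (factor income + net taxes)

    @property
    def n_sectors(self) -> int:
        return len(self.sectors)

    def tag_mask(self, tag: str) -> np.ndarray:
        return np.array([tag in self.tags.get(s, frozenset()) for s in self.sectors])


@dataclass
class CalibratedModel:
    """All regions plus the world trade pool; the CGE's full parameter set."""

    regions: list                   # list[RegionParams], shared sector order
    sectors: list
    elas: ElasticityConfig
    dw: np.ndarray                  # (R, S) world-pool shares of each exporter
    W0: np.ndarray                  # (S,) base world trade volume per commodity
    sams: list = field(default_factory=list)  # the source SAMs (for replication tests)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_sectors(self) -> int:
        return len(self.sectors)

    def region_index(self, region_id: str) -> int:
        for i, rp in enumerate(self.regions):
            if rp.region_id == region_id:
                return i
        raise KeyError(region_id)

    def tag_mask(self, tag: str) -> np.ndarray:
        return self.regions[0].tag_mask(tag)

    def world_gdp0(self) -> float:
        return float(sum(rp.GDP0 for rp in self.regions))


def _subsistence_for(tags: frozenset, shares: dict, sector: str) -> float:
    if sector in shares:
        return float(shares[sector])
    for tag in ("staple", "face_to_face", "transport", "energy"):
        if tag in tags and tag in shares:
            return float(shares[tag])
    if "perishable" in tags:
        # distinguish fruit/veg vs meat/dairy by name when possible
        if "fruit" in sector and "fruitveg" in shares:
            return float(shares["fruitveg"])
        if ("meat" in sector or "dairy" in sector) and "meatdairy" in shares:
            return float(shares["meatdairy"])
        return float(shares.get("fruitveg", 0.1))
    return float(shares.get("default", 0.0))


def _calibrate_les(
    q0: np.ndarray, p0: np.ndarray, sub: np.ndarray, f2f_mask: np.ndarray, eps_f2f: float
) -> tuple[np.ndarray, np.ndarray]:
    """Solve for (gamma, beta) given subsistence fractions, adjusting the
    face-to-face fraction so its implied own-price elasticity is ``-eps_f2f``.

    For the LES, the own-price elasticity of good c is
    ``-1 + (p_c gamma_c / E_c) (1 - beta_c)`` with ``E_c`` base spending, so
    the subsistence fraction solving for a target elasticity is
    ``(1 - eps) / (1 - beta_c)``; beta depends on gamma, hence a short fixed
    point.  The LES caps how price-elastic a large budget item can be, so the
    luxury (negative) subsistence share is bounded below; when the bound
    binds, the implied elasticity is the largest the demand system attains.
    """
    E = p0 * q0
    Ctot = float(E.sum())
    sub = sub.copy()
    for _ in range(80):
        gamma = sub * q0
        V = Ctot - float((p0 * gamma).sum())
        if V <= 0:
            raise CalibrationError("subsistence spending exceeds the consumption budget")
        beta = (E - p0 * gamma) / V
        if np.any(beta < 0):
            bad = np.where(beta < 0)[0]
            raise CalibrationError(f"negative LES marginal budget share at sectors {bad}")
        new = sub.copy()
        new[f2f_mask] = np.clip(
            (1.0 - eps_f2f) / np.maximum(1.0 - beta[f2f_mask], 1e-6), -2.0, 0.95
        )
        if np.max(np.abs(new - sub)) < 1e-12:
            sub = new
            break
        sub = new
    gamma = sub * q0
    V = Ctot - float((p0 * gamma).sum())
    beta = (E - p0 * gamma) / V
    if np.any(sub >= 1.0):
        raise CalibrationError("a subsistence share reached 1; reduce LES curvature")
    return gamma, beta


def calibrate_region(sam: SAM, elas: ElasticityConfig, region_tags=()) -> RegionParams:
    """Calibrate one region's parameters from its balanced SAM."""
    rep = balance_check(sam, tol=1e-8)
    if not rep.empty:
        raise CalibrationError(
            f"SAM {sam.region_id!r} is not balanced: {rep['account'].tolist()}"
        )
    f = sam.flows
    secs = list(sam.sectors)
    S = len(secs)
    act = [f"act_{s}" for s in secs]
    com = [f"com_{s}" for s in secs]

    X0 = np.array([f.loc[a_, c_] for a_, c_ in zip(act, com)], dtype=float)
    if np.any(X0 <= 0):
        raise CalibrationError("every activity needs positive gross output")
    io = f.loc[com, act].to_numpy(dtype=float)          # io[t, s]
    WU0 = f.loc[ULAB, act].to_numpy(dtype=float)
    WS0 = f.loc[SLAB, act].to_numpy(dtype=float)
    K0 = f.loc[CAP, act].to_numpy(dtype=float) if CAP in f.index else np.zeros(S)
    L0 = WU0 + WS0
    if np.any(L0 <= 0):
        bad = [secs[i] for i in np.where(L0 <= 0)[0]]
        raise CalibrationError(f"zero labor payment in sectors {bad}")
    VA0 = L0 + K0
    if np.any(VA0 <= 0):
        raise CalibrationError("nonpositive value added")

    labor_coef = L0 / X0
    du, ds = WU0 / L0, WS0 / L0
    mu = K0 / L0

    E0 = f.loc[com, "row"].to_numpy(dtype=float)
    M0 = f.loc["row", com].to_numpy(dtype=float)
    D0 = X0 - E0
    if np.any(D0 < -1e-9 * X0):
        raise CalibrationError("exports exceed gross output")
    D0 = np.maximum(D0, 0.0)
    Q0 = D0 + M0
    if np.any(Q0 <= 0):
        raise CalibrationError("a commodity has zero absorption")
    dd, dm = D0 / Q0, M0 / Q0

    T0 = f.loc["gov", com].to_numpy(dtype=float)
    t_com = T0 / Q0
    # SAM intermediate cells are purchaser values (tax-inclusive); the physical
    # Leontief coefficient strips the commodity tax so base unit cost is 1.
    a = io / ((1.0 + t_com)[:, None] * X0[None, :])
    C0 = f.loc[com, "hh"].to_numpy(dtype=float)
    G0 = f.loc[com, "gov"].to_numpy(dtype=float)
    I0 = f.loc[com, "sav"].to_numpy(dtype=float)
    p0 = 1.0 + t_com                                    # base purchaser price
    q_cons0 = C0 / p0
    g0 = G0 / p0
    beta_inv = I0 / I0.sum() if I0.sum() > 0 else np.zeros(S)

    sub = np.array(
        [_subsistence_for(sam.sector_tags.get(s, frozenset()), elas.subsistence_shares, s)
         for s in secs]
    )
    f2f_mask = np.array(
        [("face_to_face" in sam.sector_tags.get(s, frozenset())) for s in secs]
    )
    gamma, beta = _calibrate_les(q_cons0, p0, sub, f2f_mask, elas.f2f_demand_elasticity)

    TR0 = float(f.loc["hh", "gov"])
    TX0 = float(f.loc["gov", "hh"])
    FY0 = float(WU0.sum() + WS0.sum() + K0.sum())
    theta = TX0 / FY0
    disp0 = FY0 + TR0 - TX0
    S_h0 = float(f.loc["sav", "hh"])
    S_g0 = float(f.loc["sav", "gov"])
    F0 = float(f.loc["sav", "row"])
    if abs(disp0 - (C0.sum() + S_h0)) > 1e-6 * max(disp0, 1.0):
        raise CalibrationError("household account does not close")

    return RegionParams(
        region_id=sam.region_id, sectors=secs, tags=dict(sam.sector_tags),
        region_tags=frozenset(region_tags),
        a=a, labor_coef=labor_coef, du=du, ds=ds, mu=mu,
        X0=X0, E0=E0, M0=M0, D0=D0, dd=dd, dm=dm,
        t_com=t_com, theta=theta, TR0=TR0,
        gamma=gamma, beta=beta, q_cons0=q_cons0, C0=C0, Ctot0=float(C0.sum()),
        g0=g0, beta_inv=beta_inv, I0=I0,
        LU0=float(WU0.sum()), LS0=float(WS0.sum()), WU0=WU0, WS0=WS0, K0=K0,
        FY0=FY0, disp0=disp0, S_h0=S_h0, S_g0=S_g0, F0=F0,
        GDP0=FY0 + float(T0.sum()),
    )


def calibrate(
    sams, elas: ElasticityConfig | None = None, region_tags: dict | None = None
) -> CalibratedModel:
    """Calibrate the full model from one SAM or a list of per-region SAMs.

    World consistency (total exports = total imports per commodity) is
    required; the world trade pool's CES shares come from base export values.
    """
    if isinstance(sams, SAM):
        sams = [sams]
    if elas is None:
        elas = ElasticityConfig()
    region_tags = region_tags or {}
    secs = list(sams[0].sectors)
    for s in sams[1:]:
        if list(s.sectors) != secs:
            raise CalibrationError("all regions must share one sector list")
    regions = [
        calibrate_region(s, elas, region_tags.get(s.region_id, ())) for s in sams
    ]
    E = np.array([rp.E0 for rp in regions])
    M = np.array([rp.M0 for rp in regions])
    W0 = E.sum(axis=0)
    gap = np.abs(W0 - M.sum(axis=0))
    if np.any(gap > 1e-6 * np.maximum(W0, 1.0)):
        raise CalibrationError("world exports != world imports for some commodity")
    with np.errstate(invalid="ignore", divide="ignore"):
        dw = np.where(W0[None, :] > 0, E / np.where(W0 > 0, W0, 1.0)[None, :], 0.0)
    return CalibratedModel(regions=regions, sectors=secs, elas=elas, dw=dw, W0=W0,
                           sams=list(sams))


def cobb_douglas_limit(elas: ElasticityConfig) -> ElasticityConfig:
    """An ElasticityConfig with unit elasticities and no subsistence (LES ->
    Cobb-Douglas); calibrated shares then equal SAM cost shares."""
    zero = {k: 0.0 for k in elas.subsistence_shares}
    return replace(
        elas, sigma_labor=1.0, sigma_armington=1.0, sigma_world=1.0,
        f2f_demand_elasticity=1.0, subsistence_shares=zero,
    )
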