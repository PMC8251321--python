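"""Synthetic worlds: balanced SAMs and survey microdata for every test stage.

The generator emulates the study conditions end to end with no external data:
a small multi-region world whose sectors carry the tags the shock channels
need (staple grains, perishable fruits & vegetables and meat & dairy,
face-to-face services, transport, energy, other manufacturing), and a
household survey per region with right-skewed lognormal incomes, factor-income
compositions that reconcile to the SAM, and food expenditure shares that fall
with log income along the default Engel curve.

Every SAM is built exactly balanced from a consistent flow story (margins are
closed algebraically, so balance holds to machine precision); RAS repair is
kept as a fallback.  All randomness flows from one master seed with a
dedicated stream per region, so adding a region does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import CalibratedModel, ElasticityConfig, calibrate
from .microsim import (INTL_POVERTY_LINE, SECTOR_GROUPS, SKILLS,
                       engel_food_share)
from .sam import SAM, balance_check
from .shocks import APRIL, PandemicScenario, RegionAssumptions, SEPTEMBER

DEFAULT_SECTORS = {
    "grains": ("agrifood", "staple"),
    "fruitveg": ("agrifood", "perishable"),
    "meatdairy": ("agrifood", "perishable"),
    "services": ("face_to_face",),
    "transport": ("transport",),
    "energy": ("energy",),
    "manufacturing": (),
}


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RegionSpec:
    name: str
    tags: tuple = ()                     # region tags: developing/africa/oecd_stimulus
    gdp_scale: float = 5000.0            # billion PPP$ per year
    survey_size: int = 10_000
    median_income: float = 4.0           # PPP$ per person per day
    sigma: float = 0.9                   # lognormal spread of incomes
    rural_share: float = 0.5
    national_poverty_line: float = INTL_POVERTY_LINE

    @property
    def developing(self) -> bool:
        return "developing" in self.tags


@dataclass(frozen=True)
class WorldSpec:
    regions: tuple
    sectors: dict = field(default_factory=lambda: dict(DEFAULT_SECTORS))
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.regions) < 2:
            raise GenerationError("need at least 2 regions for trade")
        for r in self.regions:
            if r.sigma <= 0:
                raise GenerationError("income sigma must be positive")
        tags = set().union(*(set(t) for t in self.sectors.values()))
        for needed in ("agrifood", "staple", "perishable", "face_to_face",
                       "transport", "energy"):
            if needed not in tags:
                raise GenerationError(f"no sector tagged {needed!r}")

    def region_tags(self) -> dict:
        return {r.name: r.tags for r in self.regions}


def _rng(spec: WorldSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, *key])


# ---------------------------------------------------------------------------
# SAM generation
# ---------------------------------------------------------------------------

def _noisy(rng, base: np.ndarray, rel: float = 0.15) -> np.ndarray:
    return base * (1.0 + rel * (2.0 * rng.random(base.shape) - 1.0))


def _va_shares(rng, rspec: RegionSpec, sectors: list, tags: dict) -> np.ndarray:
    prior = []
    for s in sectors:
        t = tags[s]
        if "agrifood" in t:
            prior.append(0.09 if rspec.developing else 0.025)
        elif "face_to_face" in t:
            prior.append(0.20 if rspec.developing else 0.25)
        elif "transport" in t:
            prior.append(0.08)
        elif "energy" in t:
            prior.append(0.07)
        else:
            prior.append(0.42)
    v = _noisy(rng, np.array(prior))
    return v / v.sum()


def _io_coeffs(rng, sectors: list, tags: dict) -> np.ndarray:
    """Column input-cost shares b[t, s] (purchaser values per unit of output)."""
    S = len(sectors)
    b = np.zeros((S, S))
    idx = {s: i for i, s in enumerate(sectors)}
    for s in sectors:
        j = idx[s]
        for t in sectors:
            i = idx[t]
            tt = tags[t]
            if "transport" in tt:
                b[i, j] = 0.030
            elif "energy" in tt:
                b[i, j] = 0.050
            elif "face_to_face" in tt:
                b[i, j] = 0.020
            elif not tt:               # manufacturing inputs everywhere
                b[i, j] = 0.110
            elif "staple" in tt and "agrifood" in tags[s]:
                b[i, j] = 0.060       # feed/seed within the food chain
            else:
                b[i, j] = 0.010
        b[j, j] = max(b[j, j], 0.040)
    return _noisy(rng, b, 0.2)


def _allocate_exports(weights: np.ndarray, pool: np.ndarray, cap: np.ndarray
                      ) -> np.ndarray:
    """Split each commodity pool across regions by weight, capped per region."""
    R, S = weights.shape
    E = np.zeros((R, S))
    for s in range(S):
        need = pool[s]
        open_ = np.ones(R, dtype=bool)
        for _ in range(R + 1):
            if need <= 1e-15:
                break
            w = weights[:, s] * open_
            if w.sum() <= 0:
                raise GenerationError("export allocation infeasible")
            add = need * w / w.sum()
            newE = np.minimum(E[:, s] + add, cap[:, s])
            need -= float((newE - E[:, s]).sum())
            hit = newE >= cap[:, s] - 1e-15
            E[:, s] = newE
            open_ &= ~hit
        if need > 1e-9 * max(pool[s], 1.0):
            raise GenerationError("export caps below world import demand")
    return E


def generate_sam(spec: WorldSpec) -> list:
    """Generate one exactly balanced SAM per region (world-trade consistent)."""
    sectors = list(spec.sectors)
    tags = {s: frozenset(t) for s, t in spec.sectors.items()}
    S, R = len(sectors), len(spec.regions)

    VA = np.zeros((R, S)); b = np.zeros((R, S, S))
    lab_share = np.zeros((R, S)); ush = np.zeros((R, S))
    t_com = np.zeros((R, S)); mshare = np.zeros((R, S))
    for r, rspec in enumerate(spec.regions):
        rng = _rng(spec, r, 1)
        gdp_fc = 0.93 * rspec.gdp_scale
        VA[r] = _va_shares(rng, rspec, sectors, tags) * gdp_fc
        b[r] = _io_coeffs(rng, sectors, tags)
        prior_ls, prior_u, prior_m, prior_t = [], [], [], []
        for s in sectors:
            t = tags[s]
            prior_ls.append(0.72 if "agrifood" in t else
                            0.75 if "face_to_face" in t else
                            0.40 if "energy" in t else 0.58)
            # locked-down sectors (contact services, construction-heavy
            # manufacturing) are unskilled-intensive, especially where informal
            u = (0.88 if "agrifood" in t else
                 0.72 if "face_to_face" in t else
                 0.70 if "transport" in t else
                 0.35 if "energy" in t else 0.60)
            prior_u.append(min(u + (0.08 if rspec.developing else -0.10), 0.95))
            prior_m.append(0.04 if "agrifood" in t else
                           0.01 if "face_to_face" in t else
                           0.03 if "transport" in t else
                           0.20 if "energy" in t else 0.16)
            prior_t.append(0.03 if "agrifood" in t else
                           0.10 if "face_to_face" in t else 0.08)
        lab_share[r] = np.clip(_noisy(rng, np.array(prior_ls)), 0.25, 0.9)
        ush[r] = np.clip(_noisy(rng, np.array(prior_u)), 0.05, 0.97)
        mshare[r] = np.clip(_noisy(rng, np.array(prior_m)), 0.002, 0.4)
        t_com[r] = np.clip(_noisy(rng, np.array(prior_t)), 0.0, 0.3)

    # iterate: shrink IO rows that starve a commodity of final absorption
    for attempt in range(40):
        X = VA / (1.0 - b.sum(axis=1))           # (R, S)
        if np.any(b.sum(axis=1) > 0.7):
            raise GenerationError("input coefficients too large")
        IO = b * X[:, None, :]                    # purchaser values, IO[r, t, s]
        M = mshare * X
        pool = M.sum(axis=0)
        wts = X * (1.0 + 0.3 * np.arange(R)[:, None] / R)   # mild asymmetry
        E = _allocate_exports(wts, pool, 0.5 * X)
        Dabs = X - E + M
        FB = (1.0 + t_com) * Dabs - IO.sum(axis=2)
        need_fix = FB < 0.03 * (1.0 + t_com) * Dabs
        if not need_fix.any():
            break
        for r, s in zip(*np.where(need_fix)):
            b[r, s, :] *= 0.85
    else:
        raise GenerationError("could not reserve final absorption for all sectors")

    sams = []
    for r, rspec in enumerate(spec.regions):
        rng = _rng(spec, r, 2)
        gsh, ish = np.zeros(S), np.zeros(S)
        for j, s in enumerate(sectors):
            t = tags[s]
            gsh[j] = 0.20 if "face_to_face" in t else 0.04
            ish[j] = (0.36 if not t else 0.10 if "transport" in t else 0.02)
        G = gsh * FB[r]
        I = ish * FB[r]
        C = FB[r] - G - I
        T_com = float((t_com[r] * Dabs[r]).sum())
        FY = float(VA[r].sum())
        F = float(M[r].sum() - E[r].sum())
        I_total = float(I.sum())
        sav_rate = 0.15 if not rspec.developing else 0.09
        S_h = sav_rate * float(C.sum()) / (1.0 - sav_rate)
        S_g = (I_total - F) - S_h
        # transfers are a chosen share of factor income; the direct tax closes
        # the household account (it may be a net subsidy in poor regions)
        TR = (0.04 if not rspec.developing else 0.06) * FY
        TX = FY + TR - float(C.sum()) - S_h

        WU = lab_share[r] * VA[r] * ush[r]
        WS = lab_share[r] * VA[r] * (1.0 - ush[r])
        K = (1.0 - lab_share[r]) * VA[r]

        act = [f"act_{s}" for s in sectors]
        com = [f"com_{s}" for s in sectors]
        labels = act + com + ["ulab", "slab", "cap", "hh", "gov", "sav", "row"]
        f = pd.DataFrame(0.0, index=labels, columns=labels)
        for j, s in enumerate(sectors):
            f.loc[act[j], com[j]] = X[r, j]
            f.loc[com, act[j]] = IO[r, :, j]
            f.loc["ulab", act[j]] = WU[j]
            f.loc["slab", act[j]] = WS[j]
            f.loc["cap", act[j]] = K[j]
            f.loc[com[j], "hh"] = C[j]
            f.loc[com[j], "gov"] = G[j]
            f.loc[com[j], "sav"] = I[j]
            f.loc[com[j], "row"] = E[r, j]
            f.loc["row", com[j]] = M[r, j]
            f.loc["gov", com[j]] = t_com[r, j] * Dabs[r, j]
        f.loc["hh", "ulab"] = WU.sum()
        f.loc["hh", "slab"] = WS.sum()
        f.loc["hh", "cap"] = K.sum()
        f.loc["gov", "hh"] = TX
        f.loc["hh", "gov"] = TR
        f.loc["sav", "hh"] = S_h
        f.loc["sav", "gov"] = S_g
        f.loc["sav", "row"] = F

        part = {a: "activity" for a in act}
        part.update({c: "commodity" for c in com})
        part.update({"ulab": "factor", "slab": "factor", "cap": "factor",
                     "hh": "household", "gov": "government",
                     "sav": "savings", "row": "world"})
        sam = SAM(f, part, sectors, tags, rspec.name)
        rep = balance_check(sam, tol=1e-10)
        if not rep.empty:
            raise GenerationError(
                f"constructed SAM for {rspec.name} unbalanced: {rep['account'].tolist()}"
            )
        sams.append(sam)
    return sams


# ---------------------------------------------------------------------------
# survey generation
# ---------------------------------------------------------------------------

NONFOOD_SPLIT = {"face_to_face": 0.28, "transport": 0.10, "energy": 0.14,
                 "other": 0.48}


def _group_of(tagset: frozenset) -> str:
    for g in ("agrifood", "face_to_face", "transport"):
        if g in tagset:
            return g
    return "other"


def generate_survey(spec: WorldSpec, sams: list) -> pd.DataFrame:
    """Synthetic household survey for every region, reconciled to the SAMs.

    Incomes are lognormal (right-skewed); income-source shares tilt unskilled
    and agri-food sources toward poorer and rural households; food budget
    shares follow the default Engel cubic; weighted factor incomes are fitted
    to the SAM's factor payments by iterative proportional scaling and must
    land within 2%.
    """
    frames = []
    for r, (rspec, sam) in enumerate(zip(spec.regions, sams)):
        rng = _rng(spec, r, 7)
        n = rspec.survey_size
        y = rng.lognormal(np.log(rspec.median_income), rspec.sigma, n)
        pct = pd.Series(y).rank(pct=True).to_numpy()
        rural = rng.random(n) < np.clip(rspec.rural_share * (1.7 - 1.4 * pct), 0, 1)

        # income-source shares: the poorest supply mostly unskilled labor and
        # depend little on transfers; skilled wages and capital sit at the top
        # safety-net transfers are targeted at the bottom of the distribution
        u_tot = np.clip(0.84 - 0.68 * pct + 0.05 * rng.standard_normal(n), 0.03, 0.97)
        s_tot = np.clip(0.03 + 0.55 * pct + 0.05 * rng.standard_normal(n), 0.01, 0.9)
        cap = np.clip(0.03 + 0.32 * pct**3 + 0.03 * rng.standard_normal(n), 0.01, 0.6)
        tr = np.clip(0.14 - 0.09 * pct + 0.02 * rng.standard_normal(n), 0.01, 0.35)
        tot = u_tot + s_tot + cap + tr
        u_tot, s_tot, cap, tr = (v / tot for v in (u_tot, s_tot, cap, tr))

        # rural households earn the larger part of their income off-farm
        # (nonfarm services, trade, remittance-like "other"), so even they are
        # exposed to the lockdown channels; order: agrifood, f2f, transport, other
        gw_rural = np.array([0.40, 0.14, 0.10, 0.36])
        gw_urban = np.array([0.05, 0.34, 0.13, 0.48])
        gw = np.where(rural[:, None], gw_rural, gw_urban)
        gw = gw * (1.0 + 0.25 * rng.random((n, 4)))
        gw /= gw.sum(axis=1, keepdims=True)

        data = {"region": rspec.name, "area": np.where(rural, "rural", "urban"),
                "income0": y}
        for gi, g in enumerate(SECTOR_GROUPS):
            data[f"inc_unskilled_{g}"] = u_tot * gw[:, gi]
            data[f"inc_skilled_{g}"] = s_tot * gw[:, gi]
        data["inc_capital"] = cap
        data["inc_transfers"] = tr
        df = pd.DataFrame(data)

        # weights: survey income aggregates to the SAM's household receipts
        flows = sam.flows
        hh_total = float(flows.loc["hh"].sum())          # billion $/yr
        w = np.full(n, hh_total * 1e9 / (y.sum() * 365.0))
        df.insert(2, "weight", w)

        # reconcile source totals to SAM factor payments (IPF on share columns)
        targets = _sam_source_targets(sam)
        cols = list(targets)
        inc = (df["weight"] * df["income0"]).to_numpy() * 365.0 / 1e9
        shares = df[cols].to_numpy()
        tvec = np.array([targets[c] for c in cols])
        for _ in range(500):
            totals = (inc[:, None] * shares).sum(axis=0)
            ratio = np.where(totals > 0, tvec / np.where(totals > 0, totals, 1), 1.0)
            shares *= np.clip(ratio, 0.5, 2.0)   # damped IPF step
            shares /= shares.sum(axis=1, keepdims=True)
            totals = (inc[:, None] * shares).sum(axis=0)
            if np.max(np.abs(totals - tvec) / np.maximum(tvec, 1e-12)) < 5e-4:
                break
        totals = (inc[:, None] * shares).sum(axis=0)
        gap = np.max(np.abs(totals - tvec) / np.maximum(tvec, 1e-12))
        if gap > 0.02:
            raise GenerationError(
                f"survey/SAM reconciliation failed for {rspec.name}: gap {gap:.1%}"
            )
        df[cols] = shares

        # expenditure shares: Engel food share, split across food commodities
        food = engel_food_share(y, rspec.national_poverty_line)
        w_st = np.clip(0.68 - 0.33 * pct + (0.06 * rural), 0.15, 0.9)
        w_fv = np.clip(0.14 + 0.08 * pct, 0.0, None)
        w_md = np.maximum(1.0 - w_st - w_fv, 0.02)
        tot_f = w_st + w_fv + w_md
        nonfood = 1.0 - food
        nf_weight = {}
        for s in sam.sectors:
            t = sam.sector_tags[s]
            if "agrifood" in t:
                continue
            if "energy" in t:
                nf_weight[s] = NONFOOD_SPLIT["energy"]
            elif "face_to_face" in t:
                nf_weight[s] = NONFOOD_SPLIT["face_to_face"]
            elif "transport" in t:
                nf_weight[s] = NONFOOD_SPLIT["transport"]
            else:
                nf_weight[s] = NONFOOD_SPLIT["other"]
        nf_total = sum(nf_weight.values())
        for s in sam.sectors:
            t = sam.sector_tags[s]
            if "staple" in t:
                df[f"exp_{s}"] = food * w_st / tot_f
            elif "perishable" in t:
                half = w_fv if "fruit" in s else w_md
                df[f"exp_{s}"] = food * half / tot_f
            elif "agrifood" in t:
                df[f"exp_{s}"] = 0.0
            else:
                df[f"exp_{s}"] = nonfood * nf_weight[s] / nf_total
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    _validate_survey(out)
    return out


def _sam_source_targets(sam: SAM) -> dict:
    """Household income by source (billion $/yr) implied by the SAM."""
    f = sam.flows
    targets: dict = {}
    for skill, fac in (("unskilled", "ulab"), ("skilled", "slab")):
        by_group: dict = {g: 0.0 for g in SECTOR_GROUPS}
        for s in sam.sectors:
            by_group[_group_of(sam.sector_tags[s])] += float(f.loc[fac, f"act_{s}"])
        for g, v in by_group.items():
            targets[f"inc_{skill}_{g}"] = v
    targets["inc_capital"] = float(f.loc["hh", "cap"])
    targets["inc_transfers"] = float(f.loc["hh", "gov"])
    return targets


def _validate_survey(df: pd.DataFrame) -> None:
    inc_cols = [c for c in df.columns if c.startswith("inc_")]
    exp_cols = [c for c in df.columns if c.startswith("exp_")]
    if np.any(df["weight"].to_numpy() <= 0):
        raise GenerationError("nonpositive survey weight")
    for cols in (inc_cols, exp_cols):
        s = df[cols].to_numpy()
        if np.any(s < -1e-12):
            raise GenerationError("negative share")
        if np.max(np.abs(s.sum(axis=1) - 1.0)) > 1e-9:
            raise GenerationError("share columns do not sum to 1")


# ---------------------------------------------------------------------------
# the default three-region world
# ---------------------------------------------------------------------------

def default_world(template: str = APRIL, seed: int = 0,
                  survey_size: int = 10_000) -> tuple:
    """(WorldSpec, PandemicScenario) for the stock three-region world.

    One OECD-like region (12 confinement weeks, stimulus of 3.2% of GDP), one
    Africa-like developing region (8 weeks), one South-Asia-like developing
    region (12 weeks).  The September variant differs by country-specific
    shadow taxes scaled to distancing intensity.
    """
    spec = WorldSpec(
        regions=(
            RegionSpec("oecd", tags=("developed", "oecd_stimulus"),
                       gdp_scale=45_000, survey_size=survey_size,
                       median_income=55.0, sigma=0.7, rural_share=0.2,
                       national_poverty_line=20.0),
            RegionSpec("africa", tags=("developing", "africa"),
                       gdp_scale=2_600, survey_size=survey_size,
                       median_income=2.4, sigma=1.05, rural_share=0.6),
            RegionSpec("sasia", tags=("developing",),
                       gdp_scale=6_000, survey_size=survey_size,
                       median_income=3.2, sigma=0.95, rural_share=0.55),
        ),
        seed=seed,
    )
    if template == "neutral":
        return spec, PandemicScenario.neutral()
    if template not in (APRIL, SEPTEMBER):
        raise GenerationError(f"unknown template {template!r}")
    regions = {
        "oecd": RegionAssumptions(confinement_weeks=12, distancing_intensity=0.45),
        "africa": RegionAssumptions(confinement_weeks=8, distancing_intensity=0.30),
        "sasia": RegionAssumptions(confinement_weeks=12, distancing_intensity=0.80),
    }
    scenario = PandemicScenario(template=template, regions=regions)
    return spec, scenario


def build_default_model(template: str = APRIL, seed: int = 0,
                        survey_size: int = 10_000,
                        elas: ElasticityConfig | None = None):
    """Convenience: (model, survey, scenario) for the default world."""
    spec, scenario = default_world(template, seed, survey_size)
    sams = generate_sam(spec)
    survey = generate_survey(spec, sams)
    model = calibrate(sams, elas, region_tags=spec.region_tags())
    return model, survey, scenario
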