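"""Multi-region general equilibrium: system assembly, solver, and accounting.

The square system stacks, per region, zero-profit conditions (one per
activity), commodity market clearing (one per commodity), and labor market
clearing (one per skill), plus one fiscal-rule equation per deficit-rule
region.  One labor-clearing equation is redundant by Walras' law and is
replaced by the numeraire condition (world consumer price index fixed); its
residual at the solution is reported as the Walras check.

Wedges -- the face-to-face shadow tax, post-harvest perishable losses, and
the international freight margin -- are real iceberg losses: the resources
they absorb are demanded and paid for on the relevant market, so every
budget constraint balances identically and Walras' law holds to machine
precision.

The private savings response is a piecewise coping rule: households try to
cap their welfare loss at ``w`` (5%) of initial income, but cannot cut
savings by more than ``s`` (6 points) of initial income nor let savings go
negative.  Inside the solver the rule operates on CPI-deflated income so the
model stays homogeneous of degree zero in nominal scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibrate import CalibratedModel, RegionParams


class SolverError(RuntimeError):
    """Non-convergence; carries the last residual norm."""

    def __init__(self, msg: str, residual_norm: float = np.nan):
        super().__init__(msg)
        self.residual_norm = residual_norm


@dataclass(frozen=True)
class ClosureSpec:
    """Macro closure: fiscal rules, savings-rule bounds, numeraire.

    ``fiscal_rules`` maps region_id to ``"deficit"`` (deficit/GDP held at its
    base ratio via an endogenous lump-sum transfer) or ``"stimulus"``
    (exogenous transfer, endogenous deficit).  Regions not listed default by
    tag: OECD-stimulus-flagged regions get the stimulus rule, all others the
    deficit rule.
    """

    welfare_loss_cap: float = 0.05    # w: tolerated welfare loss, share of income
    max_savings_cut: float = 0.06     # s: largest savings cut, share of income
    nonnegative_savings: bool = True
    numeraire_scale: float = 1.0      # world CPI target (1 = base price level)
    fiscal_rules: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.welfare_loss_cap < 1.0):
            raise ValueError("welfare_loss_cap must be in (0,1)")
        if not (0.0 < self.max_savings_cut < 1.0):
            raise ValueError("max_savings_cut must be in (0,1)")
        if self.numeraire_scale <= 0:
            raise ValueError("numeraire scale must be positive")

    def rule_for(self, rp: RegionParams) -> str:
        r = self.fiscal_rules.get(rp.region_id)
        if r is not None:
            return r
        return "stimulus" if "oecd_stimulus" in rp.region_tags else "deficit"


def apply_savings_rule(
    income0, savings0, income1, w: float = 0.05, s: float = 0.06
):
    """Crisis savings adjustment (piecewise; vectorizes over its arguments).

    Consumption is protected down to a floor ``C0 - w*income0``; the savings
    cut is capped at ``s*income0``; savings stay within [0, savings0] and
    never exceed current income.
    """
    income0 = np.asarray(income0, dtype=float)
    savings0 = np.asarray(savings0, dtype=float)
    income1 = np.asarray(income1, dtype=float)
    lower = np.maximum(0.0, savings0 - s * income0)
    c_floor = (income0 - savings0) - w * income0
    sv = np.minimum(savings0, np.maximum(lower, income1 - c_floor))
    sv = np.minimum(sv, income1)
    sv = np.maximum(sv, 0.0)
    return sv if sv.ndim else float(sv)


# ---------------------------------------------------------------------------
# stacked parameter arrays (cached per model instance)
# ---------------------------------------------------------------------------

class _Stacked:
    def __init__(self, model: CalibratedModel):
        rs = model.regions
        st = lambda attr: np.stack([getattr(rp, attr) for rp in rs])
        sc = lambda attr: np.array([getattr(rp, attr) for rp in rs], dtype=float)
        self.A = st("a")                      # (R, S, S): A[r, t, s]
        for name in ("labor_coef", "du", "ds", "mu", "X0", "E0", "M0", "D0",
                     "dd", "dm", "t_com", "gamma", "beta", "q_cons0", "C0",
                     "g0", "beta_inv", "WU0", "WS0"):
            setattr(self, name, st(name))
        for name in ("theta", "TR0", "LU0", "LS0", "disp0", "S_h0", "S_g0",
                     "F0", "GDP0", "Ctot0"):
            setattr(self, name, sc(name))
        self.sg_ratio0 = self.S_g0 / self.GDP0
        self.cw = self.Ctot0 / self.Ctot0.sum()       # regional CPI weights
        self.p_cons0 = 1.0 + self.t_com               # base purchaser prices
        self.eu_share = self.WU0 / self.LU0[:, None]  # base employment shares
        self.es_share = self.WS0 / self.LS0[:, None]
        self.traded = model.W0 > 0


def _stacked(model: CalibratedModel) -> _Stacked:
    cache = getattr(model, "_stacked_cache", None)
    if cache is None:
        cache = _Stacked(model)
        object.__setattr__(model, "_stacked_cache", cache)
    return cache


def _ces_price(shares, prices, sigma, axis=-1):
    """Dual unit cost of a calibrated CES aggregate (Cobb-Douglas at sigma=1)."""
    if abs(sigma - 1.0) < 1e-12:
        with np.errstate(divide="ignore"):
            lg = np.where(shares > 0, np.log(np.where(prices > 0, prices, 1.0)), 0.0)
        return np.exp(np.sum(shares * lg, axis=axis))
    e = 1.0 - sigma
    return np.sum(shares * prices ** e, axis=axis) ** (1.0 / e)


# ---------------------------------------------------------------------------
# unknown vector packing
# ---------------------------------------------------------------------------

def _deficit_regions(model: CalibratedModel, closure: ClosureSpec) -> list:
    return [i for i, rp in enumerate(model.regions) if closure.rule_for(rp) == "deficit"]


def pack_benchmark(model: CalibratedModel, closure: ClosureSpec) -> np.ndarray:
    """Benchmark starting point for the unknown vector."""
    R, S = model.n_regions, model.n_sectors
    st = _stacked(model)
    nu = closure.numeraire_scale
    z = np.concatenate([
        np.log(np.full(R * S, nu)),          # pd
        np.log(st.X0.ravel()),               # X
        np.log(np.full(2 * R, nu)),          # wu, ws
        np.zeros(len(_deficit_regions(model, closure))),  # transfer adjustments
    ])
    return z


def _unpack(z, model, closure):
    R, S = model.n_regions, model.n_sectors
    i = 0
    pd_ = np.exp(z[i:i + R * S]).reshape(R, S); i += R * S
    X = np.exp(z[i:i + R * S]).reshape(R, S); i += R * S
    wu = np.exp(z[i:i + R]); i += R
    ws = np.exp(z[i:i + R]); i += R
    dev = _deficit_regions(model, closure)
    trf = np.zeros(R)
    st = _stacked(model)
    for k, r in enumerate(dev):
        trf[r] = z[i + k] * st.GDP0[r]
    return pd_, X, wu, ws, trf


def _evaluate(model, shocks, closure, pd_, X, wu, ws, trf):
    """All model quantities and scaled residuals at a candidate point."""
    st = _stacked(model)
    el = model.elas
    R, S = model.n_regions, model.n_sectors
    nu = closure.numeraire_scale

    tau = shocks.shadow_tax                          # (R, S)
    lam = shocks.perish_loss[None, :]                # (1, S)
    tfp = shocks.tfp_mult                            # (R, S)
    f = shocks.freight_margin

    # labor-nest unit cost and world/import/composite prices
    wpair = np.stack([wu, ws], axis=-1)[:, None, :]  # (R, 1, 2)
    shares = np.stack([st.du, st.ds], axis=-1)       # (R, S, 2)
    w_tilde = _ces_price(shares, wpair, el.sigma_labor)          # (R, S)
    pw = np.full(S, nu)                               # non-traded: unused
    if st.traded.any():
        pw[st.traded] = _ces_price(
            model.dw.T[st.traded], pd_.T[st.traded], el.sigma_world, axis=-1
        )
    pm = pw[None, :] * (1.0 + f)
    arm_shares = np.stack([st.dd, st.dm], axis=-1)
    arm_prices = np.stack([pd_, np.broadcast_to(pm, pd_.shape)], axis=-1)
    pq = _ces_price(arm_shares, arm_prices, el.sigma_armington)  # (R, S)

    p_int = pq * (1.0 + st.t_com) * (1.0 + tau) / (1.0 - lam)
    p_cons = p_int
    p_gov = pq * (1.0 + st.t_com) / (1.0 - lam)

    # zero profit
    int_cost = np.einsum("rts,rt->rs", st.A, p_int)
    cost = (int_cost + st.labor_coef * w_tilde * (1.0 + st.mu)) / tfp
    res_zp = (pd_ - cost) / pd_

    # labor demand and effective endowments
    lagg = st.labor_coef * X / tfp
    U = st.du * (w_tilde / wu[:, None]) ** el.sigma_labor * lagg
    Sk = st.ds * (w_tilde / ws[:, None]) ** el.sigma_labor * lagg
    exp_u = (st.eu_share * shocks.sector_exposure[None, :]).sum(axis=1)
    exp_s = (st.es_share * shocks.sector_exposure[None, :]).sum(axis=1)
    mult_u = np.clip(1.0 - shocks.labor_red_health - shocks.labor_red_dist[:, 0] * exp_u, 0.0, 1.0)
    mult_s = np.clip(1.0 - shocks.labor_red_health - shocks.labor_red_dist[:, 1] * exp_s, 0.0, 1.0)
    LU_sup = st.LU0 * mult_u
    LS_sup = st.LS0 * mult_s

    # incomes and the savings rule; labor income is valued at the effective
    # endowment (supply side), which is what makes the dropped labor-market
    # equation Walras-redundant
    cap_income = (st.mu * w_tilde * lagg).sum(axis=1)
    FY = wu * LU_sup + ws * LS_sup + cap_income
    TR = st.TR0 * nu + shocks.stimulus * nu + trf
    TX = st.theta * FY
    disp = FY + TR - TX
    P_hh = ((st.C0 / st.Ctot0[:, None]) * (p_cons / st.p_cons0)).sum(axis=1)
    if shocks.savings_rule_active:
        S_real = apply_savings_rule(
            st.disp0, st.S_h0, disp / P_hh,
            w=closure.welfare_loss_cap, s=closure.max_savings_cut,
        )
    else:
        S_real = st.S_h0
    S_h = S_real * P_hh

    # household demand (LES)
    C = disp - S_h
    V = C - (p_cons * st.gamma).sum(axis=1)
    q_cons = st.gamma + st.beta * np.maximum(V, 1e-12)[:, None] / p_cons

    # market-level composite volumes (iceberg wedges are real demands)
    wedge_hh = (1.0 + tau) / (1.0 - lam)
    int_market = np.einsum("rst,rt->rs", st.A, X / tfp) * wedge_hh
    cons_market = q_cons * wedge_hh
    gov_market = st.g0 / (1.0 - lam)
    t_over = st.beta_inv * st.t_com / (1.0 + st.t_com)
    k_inv = t_over.sum(axis=1)
    tax_other = (st.t_com * pq * (int_market + cons_market + gov_market)).sum(axis=1)
    G_val = (p_gov * st.g0).sum(axis=1)
    I_val = (S_h + tax_other + TX - G_val - TR + st.F0 * nu) / (1.0 - k_inv)
    inv_market = st.beta_inv * I_val[:, None] / (pq * (1.0 + st.t_com))
    tax_com = tax_other + k_inv * I_val
    S_g = tax_com + TX - G_val - TR
    GDP_nom = FY + tax_com

    Q = int_market + cons_market + gov_market + inv_market

    # Armington split and world pool
    D = st.dd * (pq / pd_) ** el.sigma_armington * Q
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.where(st.dm > 0, st.dm * (pq / pm) ** el.sigma_armington * Q, 0.0)
    W = (M * (1.0 + f)).sum(axis=0)
    E = np.where(
        model.dw > 0,
        model.dw * (pw[None, :] / pd_) ** el.sigma_world * W[None, :],
        0.0,
    )

    res_mkt = (X - D - E) / st.X0
    res_lu = (U.sum(axis=1) - LU_sup) / st.LU0
    res_ls = (Sk.sum(axis=1) - LS_sup) / st.LS0

    dev = _deficit_regions(model, closure)
    res_gov = np.array([
        (S_g[r] - st.sg_ratio0[r] * GDP_nom[r]) / (st.GDP0[r] * nu) for r in dev
    ])
    cpi_world = (st.cw * P_hh).sum()
    res_num = (cpi_world - nu) / nu

    # numeraire replaces the Walras-redundant equation (region 0, unskilled)
    walras = res_lu[0]
    res = np.concatenate([
        res_zp.ravel(), res_mkt.ravel(),
        np.concatenate([[res_num], res_lu[1:]]), res_ls, res_gov,
    ])

    quants = dict(
        pd=pd_, pq=pq, pw=pw, pm=pw * (1.0 + f), wu=wu, ws=ws, w_tilde=w_tilde, X=X,
        U=U, Sk=Sk, lagg=lagg, LU_sup=LU_sup, LS_sup=LS_sup,
        FY=FY, TR=TR, TX=TX, disp=disp, P_hh=P_hh, S_h=S_h, C=C,
        q_cons=q_cons, p_cons=p_cons, p_gov=p_gov, p_int=p_int,
        D=D, M=M, E=E, Q=Q, W=W,
        int_market=int_market, cons_market=cons_market, gov_market=gov_market,
        inv_market=inv_market, I_val=I_val, G_val=G_val,
        tax_com=tax_com, S_g=S_g, GDP_nom=GDP_nom,
        cap_income=cap_income, walras=walras, trf=trf, tfp=tfp,
    )
    return res, quants


def excess_demand(model, unknowns, shocks=None, closure=None) -> np.ndarray:
    """Scaled residual vector of the square system at a packed unknown vector.

    The packing is ``[log pd, log X, log wu, log ws, transfer/GDP0]`` (see
    :func:`pack_benchmark`).  Residuals are scale-free: zero profit relative
    to the output price, market clearing relative to base volumes, and the
    numeraire gap relative to its target, so the system is homogeneous of
    degree zero in the nominal scale.
    """
    closure = closure or ClosureSpec()
    if shocks is None:
        from .shocks import ShockSet
        shocks = ShockSet.neutral(model)
    res, _ = _evaluate(model, shocks, closure, *_unpack(unknowns, model, closure))
    if not np.all(np.isfinite(res)):
        raise FloatingPointError("non-finite residual: functional-form domain violation")
    return res


# ---------------------------------------------------------------------------
# equilibrium container
# ---------------------------------------------------------------------------

@dataclass
class Equilibrium:
    """A solved state: prices, quantities, incomes and fiscal accounts."""

    model: CalibratedModel
    closure: ClosureSpec
    quants: dict
    residual_norm: float
    iterations: int

    def __getattr__(self, name):
        q = object.__getattribute__(self, "quants")
        if name in q:
            return q[name]
        raise AttributeError(name)

    @property
    def region_ids(self) -> list:
        return [rp.region_id for rp in self.model.regions]

    @property
    def walras_residual(self) -> float:
        """Value of the dropped labor market's excess demand over world income."""
        q = self.quants
        ed = q["walras"] * self.model.regions[0].LU0 * q["wu"][0]
        return abs(ed) / q["GDP_nom"].sum()

    # -- value added (double deflation) ------------------------------------
    def _int_inputs(self) -> np.ndarray:
        """Real intermediate input volumes absorbed per activity (R, S)."""
        st = _stacked(self.model)
        q = self.quants
        # per activity s: sum_t A[t,s] X_s / tfp_s * wedge_t
        wedge = q["p_int"] / (q["pq"] * (1.0 + st.t_com))   # (1+tau)/(1-lam)
        return np.einsum("rt,rts,rs->rs", wedge, st.A, q["X"] / q["tfp"])

    def va_table(self):
        """(price, quantity) of double-deflated value added, arrays (R, S)."""
        q = self.quants
        qty = q["X"] - self._int_inputs()
        nominal = q["w_tilde"] * (1.0 + _stacked(self.model).mu) * q["lagg"]
        price = nominal / qty
        return price, qty

    # -- SAM replication ----------------------------------------------------
    def flows_table(self, region: int):
        """Reconstruct the region's SAM flows at this equilibrium (nominal)."""
        m, q, st = self.model, self.quants, _stacked(self.model)
        r = region
        sam0 = m.sams[r]
        f = sam0.flows.copy() * 0.0
        secs = m.sectors
        act = [f"act_{s}" for s in secs]
        com = [f"com_{s}" for s in secs]
        for j, s in enumerate(secs):
            f.loc[act[j], com[j]] = q["pd"][r, j] * q["X"][r, j]
            io_val = q["p_int"][r, :] * st.A[r, :, j] * q["X"][r, j] / q["tfp"][r, j]
            f.loc[com, act[j]] = io_val
            f.loc["ulab", act[j]] = q["wu"][r] * q["U"][r, j]
            f.loc["slab", act[j]] = q["ws"][r] * q["Sk"][r, j]
            if "cap" in f.index:
                f.loc["cap", act[j]] = st.mu[r, j] * q["w_tilde"][r, j] * q["lagg"][r, j]
        f.loc[com, "hh"] = q["p_cons"][r] * q["q_cons"][r]
        f.loc[com, "gov"] = q["p_gov"][r] * st.g0[r]
        f.loc[com, "sav"] = q["inv_market"][r] * q["pq"][r] * (1.0 + st.t_com[r])
        f.loc[com, "row"] = q["pd"][r] * q["E"][r]
        f.loc["row", com] = q["pm"] * q["M"][r]
        f.loc["gov", com] = st.t_com[r] * q["pq"][r] * q["Q"][r]
        f.loc["hh", "ulab"] = q["wu"][r] * q["U"][r].sum()
        f.loc["hh", "slab"] = q["ws"][r] * q["Sk"][r].sum()
        if "cap" in f.index:
            f.loc["hh", "cap"] = q["cap_income"][r]
        f.loc["gov", "hh"] = q["TX"][r]
        f.loc["hh", "gov"] = q["TR"][r]
        f.loc["sav", "hh"] = q["S_h"][r]
        f.loc["sav", "gov"] = q["S_g"][r]
        f.loc["sav", "row"] = st.F0[r] * self.closure.numeraire_scale
        return f

    # -- sector-group helpers ----------------------------------------------
    def employment_by_group(self) -> dict:
        """Labor use per (skill, sector-group), groups {agrifood, face_to_face,
        transport, other}."""
        m, q = self.model, self.quants
        groups = _sector_groups(m)
        out = {}
        for g, mask in groups.items():
            out[("unskilled", g)] = q["U"][:, mask].sum(axis=1)
            out[("skilled", g)] = q["Sk"][:, mask].sum(axis=1)
        return out


def _sector_groups(model: CalibratedModel) -> dict:
    ag = model.tag_mask("agrifood")
    f2f = model.tag_mask("face_to_face")
    tr = model.tag_mask("transport")
    other = ~(ag | f2f | tr)
    return {"agrifood": ag, "face_to_face": f2f, "transport": tr, "other": other}


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def _residual(z, model, shocks, closure):
    try:
        res, _ = _evaluate(model, shocks, closure, *_unpack(z, model, closure))
    except FloatingPointError:
        return None
    if not np.all(np.isfinite(res)):
        return None
    return res


def _newton(z, model, shocks, closure, tol, max_iter, damping_min):
    n = z.size
    F = _residual(z, model, shocks, closure)
    if F is None:
        raise SolverError("non-finite residual at the starting point")
    for it in range(max_iter):
        norm = np.max(np.abs(F))
        if norm < tol:
            return z, norm, it
        J = np.empty((n, n))
        h = 1e-7 * np.maximum(1.0, np.abs(z))
        for i in range(n):
            zp = z.copy()
            zp[i] += h[i]
            Fp = _residual(zp, model, shocks, closure)
            if Fp is None:
                zp[i] = z[i] - h[i]
                Fp = _residual(zp, model, shocks, closure)
                if Fp is None:
                    raise SolverError("Jacobian evaluation failed", norm)
                J[:, i] = (F - Fp) / h[i]
            else:
                J[:, i] = (Fp - F) / h[i]
        try:
            step = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -F, rcond=None)[0]
        lam = 1.0
        while lam >= damping_min:
            z_new = z + lam * step
            F_new = _residual(z_new, model, shocks, closure)
            if F_new is not None and np.max(np.abs(F_new)) < norm:
                z, F = z_new, F_new
                break
            lam *= 0.5
        else:
            raise SolverError(
                f"damping schedule exhausted at iteration {it}", norm
            )
    norm = np.max(np.abs(F))
    if norm < tol:
        return z, norm, max_iter
    raise SolverError(f"no convergence in {max_iter} iterations", norm)


def solve_equilibrium(
    model: CalibratedModel,
    shocks=None,
    closure: ClosureSpec | None = None,
    tol: float = 1e-10,
    max_iter: int = 60,
    damping_min: float = 2.0 ** -28,
    seed: int | None = None,  # API symmetry only; the solve is deterministic
    _start: np.ndarray | None = None,
) -> Equilibrium:
    """Solve the general equilibrium under a shock set.

    Damped Newton on the scaled residuals with a finite-difference Jacobian,
    started at the benchmark.  If the full shock fails, the shock is loaded
    progressively (warm-started homotopy).  Deterministic for fixed inputs.
    """
    closure = closure or ClosureSpec()
    if shocks is None:
        from .shocks import ShockSet
        shocks = ShockSet.neutral(model)
    z0 = _start if _start is not None else pack_benchmark(model, closure)
    try:
        z, norm, its = _newton(z0, model, shocks, closure, tol, max_iter, damping_min)
    except SolverError:
        z = pack_benchmark(model, closure)
        its = 0
        for alpha in (0.25, 0.5, 0.75, 0.9, 1.0):
            z, norm, k = _newton(
                z, model, shocks.scaled(alpha), closure, tol, max_iter, damping_min
            )
            its += k
    res, quants = _evaluate(model, shocks, closure, *_unpack(z, model, closure))
    return Equilibrium(model=model, closure=closure, quants=quants,
                       residual_norm=float(np.max(np.abs(res))), iterations=its)


# ---------------------------------------------------------------------------
# welfare and national accounting
# ---------------------------------------------------------------------------

def _les_price_aggregate(p: np.ndarray, beta: np.ndarray) -> float:
    """The Stone price aggregate  prod (p_c / beta_c)^beta_c  (beta=0 terms drop)."""
    mask = beta > 0
    return float(np.exp(np.sum(beta[mask] * np.log(p[mask] / beta[mask]))))


def equivalent_variation(base: Equilibrium, sim: Equilibrium, region) -> tuple:
    """Welfare change as equivalent variation at base prices.

    Returns ``(money, percent of base disposable income)``.  Computed from the
    LES (Stone-Geary) indirect utility: ``U = (C - p.gamma) / prod (p/beta)^beta``;
    the money metric is ``e(p0, U1) - e(p0, U0)``.
    """
    m = base.model
    r = m.region_index(region) if isinstance(region, str) else region
    rp = m.regions[r]
    p0, p1 = base.p_cons[r], sim.p_cons[r]
    C0, C1 = base.C[r], sim.C[r]
    U1 = (C1 - float(p1 @ rp.gamma)) / _les_price_aggregate(p1, rp.beta)
    U0 = (C0 - float(p0 @ rp.gamma)) / _les_price_aggregate(p0, rp.beta)
    agg0 = _les_price_aggregate(p0, rp.beta)
    ev = (U1 - U0) * agg0
    return float(ev), float(100.0 * ev / rp.disp0)


def real_gdp_change(base: Equilibrium, sim: Equilibrium, region=None) -> float:
    """Percent change of real GDP (Fisher quantity index over sectoral value
    added, double-deflated).  ``region=None`` aggregates the world."""
    m = base.model
    p0, q0 = base.va_table()
    p1, q1 = sim.va_table()
    if region is not None:
        r = m.region_index(region) if isinstance(region, str) else region
        sel = np.zeros(m.n_regions, dtype=bool)
        sel[r] = True
    else:
        sel = np.ones(m.n_regions, dtype=bool)
    p0, q0, p1, q1 = (x[sel].ravel() for x in (p0, q0, p1, q1))
    base_val = float(p0 @ q0)
    if base_val == 0:
        raise ZeroDivisionError("zero base GDP")
    lasp = float(p0 @ q1) / base_val
    paasche = float(p1 @ q1) / float(p1 @ q0)
    return 100.0 * (np.sqrt(lasp * paasche) - 1.0)


def fisher_quantity_change(p0, q0, p1, q1) -> float:
    """Percent Fisher quantity change for arbitrary matched price/quantity
    vectors (geometric mean of Laspeyres and Paasche quantity indices)."""
    p0, q0, p1, q1 = (np.asarray(x, dtype=float).ravel() for x in (p0, q0, p1, q1))
    lasp = float(p0 @ q1) / float(p0 @ q0)
    paasche = float(p1 @ q1) / float(p1 @ q0)
    return 100.0 * (np.sqrt(lasp * paasche) - 1.0)
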