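"""Scenario orchestration: one config in, a directory of result tables out.

A run chains generate/load -> calibrate -> build shocks -> solve -> microsim
-> decompositions -> reports.  Every numeric default in play is echoed to the
log at start, and identical config + seed reproduces identical outputs (the
CGE solve is deterministic; all sampling flows from the master seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import ElasticityConfig, calibrate
from .decomposition import channel_decomposition, poverty_three_way
from .equilibrium import (ClosureSpec, equivalent_variation,
                          fisher_quantity_change, real_gdp_change,
                          solve_equilibrium)
from .microsim import (INTL_POVERTY_LINE, diet_shift, extract_link,
                       household_price_index, poverty_headcount,
                       update_income)
from .sam import read_sam
from .shocks import APRIL, PandemicScenario, ShockSet, build_shock_set
from .synthetic import default_world, generate_sam, generate_survey

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything one scenario run needs; YAML-loadable."""

    template: str = APRIL
    seed: int = 0
    survey_size: int = 10_000
    out_dir: str = "run_out"
    poverty_line: float = INTL_POVERTY_LINE
    income_mode: str = "stochastic"     # job losses are discrete events
    decomposition_weighting: str = "persons"
    channels: tuple = ShockSet.CHANNELS
    elasticities: dict = field(default_factory=dict)
    closure: dict = field(default_factory=dict)
    outputs: tuple = ("macro", "poverty", "diet", "decomposition_channels",
                      "decomposition_poverty3")
    # optional external data (synthetic world generated when absent)
    sam_paths: dict = field(default_factory=dict)      # region_id -> csv path
    survey_path: str | None = None
    region_tags: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["channels"] = list(d["channels"])
        d["outputs"] = list(d["outputs"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _load_world(cfg: RunConfig):
    if cfg.sam_paths:
        sams = [read_sam(p, rid) for rid, p in cfg.sam_paths.items()]
        if cfg.survey_path is None:
            raise ConfigError("survey_path required when sam_paths are given")
        survey = pd.read_csv(cfg.survey_path)
        spec, scenario = default_world(cfg.template, cfg.seed, cfg.survey_size)
        tags = cfg.region_tags
        return sams, survey, scenario, tags
    spec, scenario = default_world(cfg.template, cfg.seed, cfg.survey_size)
    sams = generate_sam(spec)
    survey = generate_survey(spec, sams)
    return sams, survey, scenario, spec.region_tags()


def run(cfg: RunConfig) -> Path:
    """Execute a full scenario run; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    elas = ElasticityConfig(**cfg.elasticities)
    closure = ClosureSpec(**cfg.closure)
    log.info("run config: %s", dataclasses.asdict(cfg))
    log.info("elasticities: %s", dataclasses.asdict(elas))
    log.info("closure: %s", dataclasses.asdict(closure))

    stage = "generate"
    try:
        sams, survey, scenario, region_tags = _load_world(cfg)
        for sam in sams:
            sam.to_csv(out / f"sam_{sam.region_id}.csv")
        survey.to_csv(out / "survey.csv", index=False)

        stage = "calibrate"
        model = calibrate(sams, elas, region_tags=region_tags)

        stage = "solve-base"
        base = solve_equilibrium(model, closure=closure)

        stage = "build-shocks"
        shocks = build_shock_set(scenario, model, closure=closure)

        stage = "solve-scenario"
        sim = solve_equilibrium(model, shocks, closure=closure)

        stage = "microsim"
        link = extract_link(base, sim)
        micro_seed = (cfg.seed * 7919 + 13) % (2**31)
        incomes1 = update_income(survey, link, mode=cfg.income_mode,
                                 seed=micro_seed)
        deflators = household_price_index(survey, link)
        pov0 = poverty_headcount(survey, survey["income0"].to_numpy(),
                                 0.0, cfg.poverty_line)
        pov1 = poverty_headcount(survey, incomes1, deflators, cfg.poverty_line)

        summary: dict = {
            "template": cfg.template, "seed": cfg.seed,
            "solver": {"residual_norm": sim.residual_norm,
                       "walras_residual": sim.walras_residual},
        }

        stage = "report-macro"
        if "macro" in cfg.outputs:
            macro = _macro_table(model, base, sim)
            macro.to_csv(out / "macro_table.csv", index=False)
            summary["macro"] = macro.to_dict("records")

        stage = "report-poverty"
        if "poverty" in cfg.outputs:
            pov = _poverty_table(pov0, pov1)
            pov.to_csv(out / "poverty_table.csv", index=False)
            summary["poverty"] = {
                "base_rate_pct": pov0.headcount_rate,
                "scenario_rate_pct": pov1.headcount_rate,
                "newly_poor_millions": pov1.poor_millions - pov0.poor_millions,
                "by_region": pov.to_dict("records"),
            }

        stage = "report-diet"
        if "diet" in cfg.outputs:
            diet = diet_shift(base, sim)
            diet.to_csv(out / "diet_table.csv", index=False)
            summary["diet"] = diet.to_dict("records")

        stage = "decompose-channels"
        if "decomposition_channels" in cfg.outputs:
            gdp_tab = channel_decomposition(
                model, shocks, list(cfg.channels), real_gdp_change,
                closure=closure, base=base, full=sim,
                outcome_name="world real GDP (% change)",
            )

            def poverty_outcome(b, s):
                lk = extract_link(b, s)
                inc = update_income(survey, lk, mode=cfg.income_mode,
                                    seed=micro_seed)
                dfl = household_price_index(survey, lk)
                p = poverty_headcount(survey, inc, dfl, cfg.poverty_line)
                return p.poor_millions - pov0.poor_millions

            pov_tab = channel_decomposition(
                model, shocks, list(cfg.channels), poverty_outcome,
                closure=closure, base=base, full=sim,
                outcome_name="newly poor (millions)",
            )
            pd.concat([gdp_tab.to_frame(), pov_tab.to_frame()]).to_csv(
                out / "decomposition_channels.csv", index=False)
            summary["decomposition_channels"] = {
                gdp_tab.outcome: {"total": gdp_tab.total,
                                  **gdp_tab.contributions,
                                  "residual": gdp_tab.residual},
                pov_tab.outcome: {"total": pov_tab.total,
                                  **pov_tab.contributions,
                                  "residual": pov_tab.residual},
            }

        stage = "decompose-poverty3"
        if "decomposition_poverty3" in cfg.outputs:
            tab3, _ = poverty_three_way(
                survey, link, cfg.poverty_line,
                weighting=cfg.decomposition_weighting,
                mode=cfg.income_mode, seed=micro_seed,
            )
            tab3.to_frame().to_csv(out / "decomposition_poverty3.csv",
                                   index=False)
            summary["decomposition_poverty3"] = {
                "total_pp": tab3.total, **tab3.contributions,
            }

        cfg.to_yaml(out / "config.yaml")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float, sort_keys=True)
        return out
    except Exception as exc:
        raise RuntimeError(f"run failed at stage {stage!r}: {exc}") from exc


def _macro_table(model, base, sim) -> pd.DataFrame:
    ag = model.tag_mask("agrifood")
    p0, q0 = base.va_table()
    p1, q1 = sim.va_table()
    rows = []
    for r, rp in enumerate(model.regions):
        ev_money, ev_pct = equivalent_variation(base, sim, r)
        e0, e1 = base.E[r], sim.E[r]
        rows.append({
            "region": rp.region_id,
            "real_consumption_EV_pct": ev_pct,
            "real_gdp_pct": real_gdp_change(base, sim, r),
            "agrifood_gdp_pct": fisher_quantity_change(
                p0[r, ag], q0[r, ag], p1[r, ag], q1[r, ag]),
            "export_volume_pct": 100.0 * (float(base.pd[r] @ e1)
                                          / float(base.pd[r] @ e0) - 1.0),
            "agrifood_export_volume_pct": 100.0 * (
                float(base.pd[r, ag] @ e1[ag])
                / max(float(base.pd[r, ag] @ e0[ag]), 1e-12) - 1.0),
        })
    ev_w = sum(equivalent_variation(base, sim, r)[0]
               for r in range(model.n_regions))
    disp_w = sum(rp.disp0 for rp in model.regions)
    rows.append({
        "region": "world",
        "real_consumption_EV_pct": 100.0 * ev_w / disp_w,
        "real_gdp_pct": real_gdp_change(base, sim),
        "agrifood_gdp_pct": fisher_quantity_change(
            p0[:, ag], q0[:, ag], p1[:, ag], q1[:, ag]),
        "export_volume_pct": 100.0 * (float((base.pd * sim.E).sum())
                                      / float((base.pd * base.E).sum()) - 1.0),
        "agrifood_export_volume_pct": 100.0 * (
            float((base.pd[:, ag] * sim.E[:, ag]).sum())
            / float((base.pd[:, ag] * base.E[:, ag]).sum()) - 1.0),
    })
    return pd.DataFrame(rows)


def _poverty_table(pov0, pov1) -> pd.DataFrame:
    b = pov0.by_region.set_index(["region", "area"])
    s = pov1.by_region.set_index(["region", "area"])
    df = pd.DataFrame({
        "base_millions": b["poor_millions"],
        "scenario_millions": s["poor_millions"],
    })
    df["change_millions"] = df["scenario_millions"] - df["base_millions"]
    df["change_pct"] = 100.0 * df["change_millions"] / df["base_millions"].where(
        df["base_millions"] > 0)
    return df.reset_index()


def compare_runs(run_a, run_b) -> pd.DataFrame:
    """Side-by-side difference of every shared numeric metric of two runs."""
    def load(p):
        with open(Path(p) / "summary.json") as fh:
            return json.load(fh)

    def flatten(d, prefix=""):
        out = {}
        if isinstance(d, dict):
            for k, v in d.items():
                out.update(flatten(v, f"{prefix}{k}/"))
        elif isinstance(d, list):
            for i, v in enumerate(d):
                if isinstance(v, dict):
                    key = "_".join(str(v[k]) for k in ("region", "area", "group")
                                   if k in v) or str(i)
                else:
                    key = str(i)
                out.update(flatten(v, f"{prefix}{key}/"))
        elif isinstance(d, (int, float)) and not isinstance(d, bool):
            if np.isfinite(d):
                out[prefix.rstrip("/")] = float(d)
        return out

    a, b = flatten(load(run_a)), flatten(load(run_b))
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ConfigError("runs share no numeric metrics (schema mismatch)")
    return pd.DataFrame({
        "metric": shared,
        "run_a": [a[k] for k in shared],
        "run_b": [b[k] for k in shared],
        "difference": [a[k] - b[k] for k in shared],
    })
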