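"""Shared fixtures: toy SAMs, oracle economies, and one solved default world.

The heavyweight objects (generated world, calibrated model, solved base and
April equilibria) are session-scoped so the directional and acceptance tests
share a single set of solves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epicge import (ClosureSpec, ElasticityConfig, build_shock_set, calibrate,
                    cobb_douglas_limit, solve_equilibrium)
from epicge.sam import SAM
from epicge.synthetic import default_world, generate_sam, generate_survey

SEED = 1


# ---------------------------------------------------------------------------
# toy SAM builders
# ---------------------------------------------------------------------------

def _partition(act, com):
    part = {a: "activity" for a in act}
    part.update({c: "commodity" for c in com})
    part.update({"ulab": "factor", "slab": "factor", "cap": "factor",
                 "hh": "household", "gov": "government",
                 "sav": "savings", "row": "world"})
    return part


def make_toy_sam(region_id="toy") -> SAM:
    """Tiny balanced 2-sector closed economy with all account classes."""
    sectors = ["food", "services"]
    act = [f"act_{s}" for s in sectors]
    com = [f"com_{s}" for s in sectors]
    labels = act + com + ["ulab", "slab", "cap", "hh", "gov", "sav", "row"]
    f = pd.DataFrame(0.0, index=labels, columns=labels)
    # food: output 100 = 10 intermediates + 90 VA; services: 120 = 20 + 100
    f.loc["act_food", "com_food"] = 100.0
    f.loc["act_services", "com_services"] = 120.0
    f.loc["com_services", "act_food"] = 10.0
    f.loc["com_food", "act_services"] = 20.0
    f.loc["ulab", "act_food"] = 60.0
    f.loc["slab", "act_food"] = 20.0
    f.loc["cap", "act_food"] = 10.0
    f.loc["ulab", "act_services"] = 40.0
    f.loc["slab", "act_services"] = 40.0
    f.loc["cap", "act_services"] = 20.0
    f.loc["hh", "ulab"] = 100.0
    f.loc["hh", "slab"] = 60.0
    f.loc["hh", "cap"] = 30.0
    # commodity balances: food 100 supply+0 tax = 20 io + C; services likewise
    f.loc["com_food", "hh"] = 70.0
    f.loc["com_food", "gov"] = 5.0
    f.loc["com_food", "sav"] = 5.0
    f.loc["com_services", "hh"] = 90.0
    f.loc["com_services", "gov"] = 10.0
    f.loc["com_services", "sav"] = 10.0
    # government: direct tax 20 funds G 15 + transfers 3 + saving 2
    f.loc["gov", "hh"] = 20.0
    f.loc["hh", "gov"] = 3.0
    f.loc["sav", "hh"] = 13.0
    f.loc["sav", "gov"] = 2.0
    tags = {"food": frozenset({"agrifood", "staple"}),
            "services": frozenset({"face_to_face"})}
    return SAM(f, _partition(act, com), sectors, tags, region_id)


def make_labor_only_sam(region_id="oracle", beta=(0.4, 0.6), L=100.0,
                        trade_share=0.0, sectors=("alpha", "beta")) -> SAM:
    """Labor-only Cobb-Douglas oracle economy: no intermediates, no capital,
    no government activity, no savings; optionally symmetric trade."""
    s1, s2 = sectors
    act = [f"act_{s1}", f"act_{s2}"]
    com = [f"com_{s1}", f"com_{s2}"]
    labels = act + com + ["ulab", "slab", "cap", "hh", "gov", "sav", "row"]
    f = pd.DataFrame(0.0, index=labels, columns=labels)
    out = np.array(beta) * L
    for j, s in enumerate((s1, s2)):
        f.loc[f"act_{s}", f"com_{s}"] = out[j]
        f.loc["ulab", f"act_{s}"] = out[j] / 2
        f.loc["slab", f"act_{s}"] = out[j] / 2
        e = trade_share * out[j]
        f.loc[f"com_{s}", "row"] = e          # exports
        f.loc["row", f"com_{s}"] = e          # imports (balanced trade)
        f.loc[f"com_{s}", "hh"] = out[j]      # consumption = supply - E + M
    f.loc["hh", "ulab"] = L / 2
    f.loc["hh", "slab"] = L / 2
    tags = {s1: frozenset(), s2: frozenset()}
    return SAM(f, _partition(act, com), [s1, s2], tags, region_id)


@pytest.fixture
def toy_sam():
    return make_toy_sam()


# ---------------------------------------------------------------------------
# the default synthetic world, solved once
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def world():
    spec, scenario = default_world(seed=SEED, survey_size=8_000)
    sams = generate_sam(spec)
    survey = generate_survey(spec, sams)
    model = calibrate(sams, region_tags=spec.region_tags())
    return {"spec": spec, "scenario": scenario, "sams": sams,
            "survey": survey, "model": model}


@pytest.fixture(scope="session")
def base_eq(world):
    return solve_equilibrium(world["model"])


@pytest.fixture(scope="session")
def april(world, base_eq):
    """Full April-template shock set and solved equilibrium."""
    model = world["model"]
    shocks = build_shock_set(world["scenario"], model)
    eq = solve_equilibrium(model, shocks)
    return {"shocks": shocks, "eq": eq}


@pytest.fixture(scope="session")
def cobb_oracle_1r():
    """1-region labor-only Cobb-Douglas economy and its calibrated model."""
    sam = make_labor_only_sam()
    return calibrate([sam], elas=cobb_douglas_limit(ElasticityConfig()))


@pytest.fixture(scope="session")
def cobb_oracle_2r():
    """2 symmetric trading regions, Cobb-Douglas everywhere."""
    sams = [make_labor_only_sam("west", trade_share=0.2),
            make_labor_only_sam("east", trade_share=0.2)]
    return calibrate(sams, elas=cobb_douglas_limit(ElasticityConfig()))
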