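"""Social accounting matrices: container, balance checking and biproportional repair.

A SAM is a square table of monetary flows among the accounts of one region:
production activities, commodity markets, primary factors, a representative
household, the government, a savings–investment account, and the rest of the
world.  Row total = column total for every account in a balanced SAM; that
identity is what the CGE calibration replicates at zero shock.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: account classes a SAM partition must declare
ACCOUNT_CLASSES = (
    "activity",
    "commodity",
    "factor",
    "household",
    "government",
    "savings",
    "world",
)

#: factor labels used throughout the package
ULAB, SLAB, CAP = "ulab", "slab", "cap"

#: sector tag vocabulary (a sector may carry several tags)
SECTOR_TAGS = (
    "agrifood",      # part of the essential agri-food chain
    "staple",        # basic staple food
    "perishable",    # fruits & vegetables, meat & dairy
    "face_to_face",  # high-contact services
    "transport",
    "energy",
)


class SAMError(ValueError):
    """Raised for malformed or inconsistent SAM inputs."""


@dataclass
class SAM:
    """A labelled square flow matrix for one region.

    Parameters
    ----------
    flows
        Square DataFrame; ``flows.loc[i, j]`` is the payment from column
        account *j* to row account *i* (row receives, column pays).
    partition
        Mapping account label -> account class (one of ``ACCOUNT_CLASSES``).
    sectors
        Ordered sector names; activity accounts are ``act_<s>`` and commodity
        accounts ``com_<s>``.
    sector_tags
        Mapping sector -> set of tags from ``SECTOR_TAGS``.
    region_id
        Region label.
    """

    flows: pd.DataFrame
    partition: Mapping[str, str]
    sectors: Sequence[str]
    sector_tags: Mapping[str, frozenset] = field(default_factory=dict)
    region_id: str = "region"

    def __post_init__(self) -> None:
        f = self.flows
        if f.shape[0] != f.shape[1]:
            raise SAMError(f"SAM must be square, got {f.shape}")
        if list(f.index) != list(f.columns):
            raise SAMError("row labels differ from column labels")
        unknown = set(f.index) - set(self.partition)
        if unknown:
            raise SAMError(f"accounts without a declared class: {sorted(unknown)}")
        bad = {a: c for a, c in self.partition.items() if c not in ACCOUNT_CLASSES}
        if bad:
            raise SAMError(f"unknown account classes: {bad}")
        self._check_sign_conventions()

    # -- structure ---------------------------------------------------------
    @property
    def accounts(self) -> list[str]:
        return list(self.flows.index)

    def accounts_of(self, cls: str) -> list[str]:
        return [a for a in self.accounts if self.partition[a] == cls]

    def tagged(self, tag: str) -> list[str]:
        return [s for s in self.sectors if tag in self.sector_tags.get(s, frozenset())]

    def _check_sign_conventions(self) -> None:
        # Only cells paid to / from the government may be negative (net taxes,
        # subsidies, deficits); every real flow is nonnegative.
        f = self.flows
        gov = set(self.accounts_of("government"))
        sav = set(self.accounts_of("savings"))
        for i in f.index:
            for j in f.columns:
                v = f.loc[i, j]
                if v < 0 and not (i in gov or j in gov or (i in sav)):
                    raise SAMError(
                        f"negative flow {v:g} in nonnegative cell ({i}, {j})"
                    )

    # -- totals ------------------------------------------------------------
    def row_totals(self) -> pd.Series:
        return self.flows.sum(axis=1)

    def col_totals(self) -> pd.Series:
        return self.flows.sum(axis=0)

    def value_added(self, sector: str) -> float:
        facs = self.accounts_of("factor")
        return float(self.flows.loc[facs, f"act_{sector}"].sum())

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.flows.to_csv(path)


def _default_partition(labels: Iterable[str]) -> dict[str, str]:
    """Infer the account class from conventional label prefixes."""
    part: dict[str, str] = {}
    known = {"hh": "household", "gov": "government", "sav": "savings", "row": "world"}
    for a in labels:
        if a.startswith("act_"):
            part[a] = "activity"
        elif a.startswith("com_"):
            part[a] = "commodity"
        elif a in (ULAB, SLAB, CAP):
            part[a] = "factor"
        elif a in known:
            part[a] = known[a]
        else:
            raise SAMError(f"unknown account label {a!r}; provide an explicit partition")
    return part


def read_sam(
    path: str | Path,
    region_id: str,
    partition: Mapping[str, str] | None = None,
    sector_tags: Mapping[str, Iterable[str]] | None = None,
) -> SAM:
    """Read a SAM from CSV (first row/column = account labels).

    The account partition is inferred from the conventional prefixes
    (``act_``/``com_``, factor names, ``hh``/``gov``/``sav``/``row``) unless
    given explicitly.  Balance is *not* assumed: run :func:`balance_check`.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise SAMError(f"non-square table {df.shape} in {path}")
    if list(df.index) != list(df.columns):
        raise SAMError(f"row labels != column labels in {path}")
    part = dict(partition) if partition is not None else _default_partition(df.index)
    sectors = [a[4:] for a in df.index if part.get(a) == "activity"]
    tags = {
        s: frozenset(sector_tags.get(s, ())) if sector_tags else frozenset()
        for s in sectors
    }
    return SAM(df.astype(float), part, sectors, tags, region_id)


def balance_check(sam: SAM, tol: float = 1e-8) -> pd.DataFrame:
    """Report accounts whose row and column totals disagree.

    Returns a DataFrame (account, row_total, col_total, rel_gap) with one row
    per account for which ``|row-col| / max(|row|,|col|) > tol``.  An all-zero
    account (0/0) is treated as balanced.
    """
    rows = sam.row_totals()
    cols = sam.col_totals()
    out = []
    for a in sam.accounts:
        r, c = float(rows[a]), float(cols[a])
        scale = max(abs(r), abs(c))
        gap = 0.0 if scale == 0.0 else abs(r - c) / scale
        if gap > tol:
            out.append({"account": a, "row_total": r, "col_total": c, "rel_gap": gap})
    return pd.DataFrame(out, columns=["account", "row_total", "col_total", "rel_gap"])


def balance_report_jsonl(report: pd.DataFrame, path: str | Path) -> None:
    """Write a balance report as JSON lines, one record per flagged account."""
    with open(path, "w") as fh:
        for rec in report.to_dict("records"):
            fh.write(json.dumps(rec) + "\n")


def ras_balance(
    matrix: np.ndarray,
    row_targets: np.ndarray,
    col_targets: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Biproportional (RAS) scaling of a nonnegative matrix to given margins.

    Alternately scales rows and columns until every margin matches its target
    within ``tol`` (relative).  Zero cells stay zero; a zero row or column with
    a positive target is structurally infeasible.
    """
    a = np.asarray(matrix, dtype=float).copy()
    r = np.asarray(row_targets, dtype=float)
    c = np.asarray(col_targets, dtype=float)
    if a.ndim != 2 or a.shape != (r.size, c.size):
        raise SAMError("matrix/target dimensions disagree")
    if np.any(a < 0) or np.any(r < 0) or np.any(c < 0):
        raise SAMError("RAS requires nonnegative matrix and targets")
    tot_r, tot_c = r.sum(), c.sum()
    scale = max(tot_r, tot_c, 1.0)
    if abs(tot_r - tot_c) > 1e-9 * scale:
        raise SAMError(f"inconsistent margins: rows sum {tot_r:g}, cols sum {tot_c:g}")
    if np.any((a.sum(axis=1) == 0) & (r > 0)) or np.any((a.sum(axis=0) == 0) & (c > 0)):
        raise SAMError("structurally infeasible: zero row/column with positive target")

    def _gap(m: np.ndarray) -> float:
        rs, cs = m.sum(axis=1), m.sum(axis=0)
        dr = np.abs(rs - r) / np.maximum(np.maximum(np.abs(r), np.abs(rs)), 1e-300)
        dc = np.abs(cs - c) / np.maximum(np.maximum(np.abs(c), np.abs(cs)), 1e-300)
        dr[(r == 0) & (rs == 0)] = 0.0
        dc[(c == 0) & (cs == 0)] = 0.0
        return float(max(dr.max(initial=0.0), dc.max(initial=0.0)))

    for _ in range(max_iter):
        if _gap(a) <= tol:
            return a
        rs = a.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            a *= np.where(rs > 0, r / np.where(rs > 0, rs, 1.0), 0.0)[:, None]
        cs = a.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            a *= np.where(cs > 0, c / np.where(cs > 0, cs, 1.0), 0.0)[None, :]
    if _gap(a) <= tol:
        return a
    raise SAMError(f"RAS did not converge in {max_iter} iterations (gap {_gap(a):.2e})")
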