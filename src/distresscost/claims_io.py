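"""Panel/claims text formats, CPI deflation to 2019 AUD, and cost aggregation.

The claims table holds one row per Medicare service line: MBS (medical
services: GP, specialist, allied health, pathology, ...) or PBS (subsidised
prescriptions), with the government benefit paid and the patient's
out-of-pocket amount.  Hospital MBS lines are excluded from cost totals by
default, so "total cost" means annual non-hospital MBS + PBS benefits in
2019 Australian dollars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PANEL_COLUMNS = ["id", "wave", "year", "k10", "age", "marital", "education",
                 "unemployed", "income_mgmt", "healthcare_card", "residence",
                 "state", "survey_month"]
CLAIMS_COLUMNS = ["id", "date", "scheme", "category", "benefit", "oop"]

MBS_CATEGORIES = ("GP", "specialist", "specialist_psychiatry", "allied",
                  "allied_mh", "pathology", "imaging", "other", "hospital")
PBS_CATEGORIES = ("PBS_antidepressant", "PBS_other")
ALL_CATEGORIES = MBS_CATEGORIES + PBS_CATEGORIES

# raw category -> reporting group used in the annual cost table
DEFAULT_CATEGORY_LOOKUP = {
    "GP": "gp",
    "specialist": "specialist",
    "specialist_psychiatry": "specialist",
    "allied": "allied",
    "allied_mh": "allied",
    "pathology": "pathology",
    "imaging": "other",
    "other": "other",
    "PBS_antidepressant": "pbs",
    "PBS_other": "pbs",
}
# categories whose out-of-pocket amounts count as mental-health related
MH_OOP_CATEGORIES = ("specialist_psychiatry", "allied_mh")


class ValidationError(ValueError):
    """Raised when an input table violates the declared format."""


@dataclass(frozen=True)
class DeflatorTable:
    """CPI index by calendar year with a declared base year (2019)."""

    index: dict
    base_year: int = 2019

    def __post_init__(self) -> None:
        if self.base_year not in self.index:
            raise ValidationError(f"base year {self.base_year} missing from deflator table")
        bad = {y: v for y, v in self.index.items() if not v > 0}
        if bad:
            raise ValidationError(f"CPI indices must be positive: {bad}")

    def factor(self, year) -> np.ndarray:
        """Multiplier taking a nominal amount in ``year`` to base-year dollars."""
        years = np.atleast_1d(np.asarray(year, dtype=int))
        missing = sorted({int(y) for y in years} - set(self.index))
        if missing:
            raise ValidationError(f"year(s) not in deflator table: {missing}")
        base = self.index[self.base_year]
        out = np.array([base / self.index[int(y)] for y in years])
        return out


def deflate(amount, year, table: DeflatorTable):
    """Convert a nominal amount to base-year (2019) dollars: amount x I(base)/I(year)."""
    a = np.asarray(amount, dtype=float)
    f = table.factor(year)
    out = a * (f if a.shape else f[0])
    return float(out) if np.isscalar(amount) else out


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} file missing required column(s): {missing}")


def read_panel(path) -> pd.DataFrame:
    """Read and validate the woman-wave panel table.

    Line numbers in error messages are 1-based data rows (header excluded).
    """
    df = pd.read_csv(path)
    _require_columns(df, PANEL_COLUMNS, "panel")
    dup = df.duplicated(subset=["id", "wave"])
    if dup.any():
        rows = (df.index[dup] + 1).tolist()
        raise ValidationError(f"duplicate (id, wave) at data row(s) {rows[:10]}")
    bad_k10 = ~df["k10"].between(10, 50)
    if bad_k10.any():
        rows = (df.index[bad_k10] + 1).tolist()
        raise ValidationError(f"k10 outside [10, 50] at data row(s) {rows[:10]}")
    bad_month = ~df["survey_month"].between(1, 12)
    if bad_month.any():
        rows = (df.index[bad_month] + 1).tolist()
        raise ValidationError(f"survey_month outside [1, 12] at data row(s) {rows[:10]}")
    return df


def read_claims(path) -> pd.DataFrame:
    """Read and validate the claim-line table (ISO dates, AUD amounts >= 0)."""
    df = pd.read_csv(path)
    _require_columns(df, CLAIMS_COLUMNS, "claims")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    bad_scheme = ~df["scheme"].isin(["MBS", "PBS"])
    if bad_scheme.any():
        raise ValidationError(
            f"unknown scheme at data row(s) {(df.index[bad_scheme] + 1).tolist()[:10]}")
    bad_cat = ~df["category"].isin(ALL_CATEGORIES)
    if bad_cat.any():
        raise ValidationError(
            f"unknown category at data row(s) {(df.index[bad_cat] + 1).tolist()[:10]}")
    is_pbs_cat = df["category"].isin(PBS_CATEGORIES)
    mismatch = (is_pbs_cat != (df["scheme"] == "PBS"))
    if mismatch.any():
        raise ValidationError(
            f"scheme/category mismatch at data row(s) {(df.index[mismatch] + 1).tolist()[:10]}")
    if (df["benefit"] < 0).any() or (df["oop"] < 0).any():
        neg = (df["benefit"] < 0) | (df["oop"] < 0)
        raise ValidationError(
            f"negative amount at data row(s) {(df.index[neg] + 1).tolist()[:10]}")
    return df


def write_panel(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in PANEL_COLUMNS if c in df.columns])


def write_claims(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=CLAIMS_COLUMNS)


@dataclass
class AnnualAggregate:
    """Annual deflated cost table plus claims that matched no panel year."""

    costs: pd.DataFrame
    unassigned: pd.DataFrame = field(repr=False, default=None)


COST_COLUMNS = ["total", "mbs", "pbs", "gp", "specialist", "allied", "pathology",
                "other", "oop_total", "oop_mbs", "oop_pbs",
                "oop_mh_allied_specialist", "oop_non_mh"]


def aggregate_annual(claims: pd.DataFrame, panel: pd.DataFrame,
                     deflators: DeflatorTable, drop_hospital: bool = True,
                     category_lookup: dict | None = None) -> AnnualAggregate:
    """Aggregate claim lines into a per (id, wave) annual cost table in 2019 AUD.

    A claim is assigned to the woman's wave whose calendar year contains the
    service date.  Claims dated outside any of the woman's panel years are
    returned in ``unassigned`` rather than silently dropped.  Women with a
    panel row but no claims get an all-zero row.
    """
    lookup = dict(DEFAULT_CATEGORY_LOOKUP if category_lookup is None else category_lookup)
    key = panel[["id", "wave", "year"]].copy()
    c = claims.copy()
    c["year"] = pd.to_datetime(c["date"]).dt.year
    merged = c.merge(key, on=["id", "year"], how="left")
    unassigned = merged[merged["wave"].isna()].drop(columns=["wave"])
    m = merged[merged["wave"].notna()].copy()
    if drop_hospital:
        m = m[m["category"] != "hospital"]
    m["benefit_real"] = m["benefit"].to_numpy() * deflators.factor(m["year"].to_numpy())
    m["oop_real"] = m["oop"].to_numpy() * deflators.factor(m["year"].to_numpy())
    m["group"] = m["category"].map(lookup)
    if m["group"].isna().any():
        missing = sorted(m.loc[m["group"].isna(), "category"].unique())
        raise ValidationError(f"category lookup has no entry for: {missing}")

    base = key.set_index(["id", "wave"])
    by_group = (m.pivot_table(index=["id", "wave"], columns="group",
                              values="benefit_real", aggfunc="sum")
                .reindex(base.index).fillna(0.0))
    for g in ["gp", "specialist", "allied", "pathology", "other", "pbs"]:
        if g not in by_group:
            by_group[g] = 0.0
    out = base.copy()
    for g in ["gp", "specialist", "allied", "pathology", "other", "pbs"]:
        out[g] = by_group[g]
    out["mbs"] = out[["gp", "specialist", "allied", "pathology", "other"]].sum(axis=1)
    out["total"] = out["mbs"] + out["pbs"]

    m["is_mh_oop"] = m["category"].isin(MH_OOP_CATEGORIES)
    m["is_pbs"] = m["scheme"] == "PBS"
    oop = m.groupby(["id", "wave"]).apply(
        lambda g: pd.Series({
            "oop_total": g["oop_real"].sum(),
            "oop_mbs": g.loc[~g["is_pbs"], "oop_real"].sum(),
            "oop_pbs": g.loc[g["is_pbs"], "oop_real"].sum(),
            "oop_mh_allied_specialist": g.loc[g["is_mh_oop"], "oop_real"].sum(),
            "oop_non_mh": g.loc[~g["is_mh_oop"], "oop_real"].sum(),
        }), include_groups=False).reindex(base.index).fillna(0.0)
    for col in oop.columns:
        out[col] = oop[col]

    out = out.reset_index()
    out["positive_total"] = out["total"] > 0
    out["positive_mbs"] = out["mbs"] > 0
    out["positive_pbs"] = out["pbs"] > 0
    for g in ["gp", "specialist", "allied", "pathology", "other"]:
        out[f"positive_{g}"] = out[g] > 0
    out["positive_oop_total"] = out["oop_total"] > 0
    out["positive_oop_mbs"] = out["oop_mbs"] > 0
    out["positive_oop_pbs"] = out["oop_pbs"] > 0
    out["positive_oop_mh_allied_specialist"] = out["oop_mh_allied_specialist"] > 0
    out["positive_oop_non_mh"] = out["oop_non_mh"] > 0
    cols = ["id", "wave", "year"] + COST_COLUMNS + [c for c in out.columns
                                                    if c.startswith("positive_")]
    return AnnualAggregate(costs=out[cols], unassigned=unassigned.reset_index(drop=True))


def aggregate_window(claims: pd.DataFrame, panel: pd.DataFrame, k: int,
                     deflators: DeflatorTable, drop_hospital: bool = True) -> pd.DataFrame:
    """Total deflated cost in the k-month window starting at each survey month.

    For a woman whose survey for a wave was returned in calendar month m of
    year y, T_k is the deflated sum of her claims in months m, m+1, ...,
    m+k-1, rolling over the year boundary.  Returns columns id, wave, window_cost.
    """
    if not (1 <= int(k) <= 12):
        raise ValueError(f"window length k must be in 1..12, got {k}")
    k = int(k)
    c = claims.copy()
    if drop_hospital:
        c = c[c["category"] != "hospital"]
    d = pd.to_datetime(c["date"])
    c["month_index"] = d.dt.year * 12 + (d.dt.month - 1)
    c["claim_year"] = d.dt.year
    c["real"] = c["benefit"].to_numpy() * deflators.factor(d.dt.year.to_numpy())

    rows = []
    claims_by_id = dict(tuple(c.groupby("id")))
    for _, p in panel.iterrows():
        start = int(p["year"]) * 12 + (int(p["survey_month"]) - 1)
        cc = claims_by_id.get(p["id"])
        if cc is None:
            total = 0.0
        else:
            in_win = (cc["month_index"] >= start) & (cc["month_index"] < start + k)
            total = float(cc.loc[in_win, "real"].sum())
        rows.append({"id": p["id"], "wave": p["wave"], "window_cost": total})
    return pd.DataFrame(rows)
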