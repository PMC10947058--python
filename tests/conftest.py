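"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest

import distresscost as dc


@pytest.fixture(scope="session")
def default_sim():
    """One realization of the default study conditions (2,000 women x 5 waves)."""
    return dc.simulate_panel(dc.SimConfig(n_women=2000, seed=11), with_claims=False)


@pytest.fixture(scope="session")
def claims_sim():
    """Smaller realization including claim-line expansion."""
    return dc.simulate_panel(dc.SimConfig(n_women=300, seed=5), with_claims=True)


@pytest.fixture(scope="session")
def deflators():
    return dc.DeflatorTable(index=dict(dc.SimConfig().cpi_by_year))


def make_panel(rows):
    """Panel frame from dicts, filling unspecified covariates with constants."""
    defaults = {"age": 20, "marital": "never_married", "education": "degree",
                "unemployed": 0, "income_mgmt": 0, "healthcare_card": 0,
                "residence": "metro", "state": "NSW", "survey_month": 5}
    out = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        d.setdefault("year", 2012 + d["wave"])
        out.append(d)
    return pd.DataFrame(out)


def make_claims(rows):
    defaults = {"scheme": "MBS", "category": "GP", "oop": 0.0}
    out = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        out.append(d)
    df = pd.DataFrame(out)
    df["date"] = pd.to_datetime(df["date"])
    return df


@pytest.fixture
def flat_cpi():
    return dc.DeflatorTable(index={y: 100.0 for y in range(2010, 2021)})


def pattern_panel(patterns, distress_score=30, calm_score=15):
    """Balanced 5-wave panel from '01011'-style distress patterns per woman."""
    rows = []
    for i, pat in enumerate(patterns):
        for w, ch in enumerate(pat, start=1):
            rows.append({"id": i + 1, "wave": w,
                         "k10": distress_score if ch == "1" else calm_score})
    return make_panel(rows)
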