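"""Descriptive summaries: mean costs by distress level, level contrasts, and a
nonparametric cost-K10 curve (Nadaraya-Watson local mean, Gaussian kernel)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .distress_coding import DEFAULT_CUTOFFS, DistressCutoffs, k10_levels, LEVELS


def cost_summary_by_level(costs: pd.DataFrame, panel: pd.DataFrame,
                          cutoffs: DistressCutoffs = DEFAULT_CUTOFFS,
                          outcome: str = "total") -> pd.DataFrame:
    """Per-level (and full-sample) mean, SE of mean, % nonzero, conditional mean.

    SEs are simple SD/sqrt(n) (descriptive, unclustered).  Empty levels are
    reported with n=0 and NaN statistics rather than raising.
    """
    df = panel[["id", "wave", "k10"]].merge(costs, on=["id", "wave"], how="inner")
    df["level"] = k10_levels(df["k10"].to_numpy(), cutoffs)
    out = {}
    groups = [("full", df)] + [(lv, df[df["level"] == lv]) for lv in LEVELS]
    for name, g in groups:
        x = g[outcome].to_numpy(dtype=float)
        n = len(x)
        nz = x[x > 0]
        out[name] = {
            "n": n,
            "mean": float(np.mean(x)) if n else np.nan,
            "se": float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "pct_nonzero": 100.0 * len(nz) / n if n else np.nan,
            "mean_nonzero": float(np.mean(nz)) if len(nz) else np.nan,
        }
    return pd.DataFrame(out).T


def level_contrasts(summary: pd.DataFrame, reference: str = "none") -> pd.DataFrame:
    """Dollar and percent differences of each level's mean vs the reference level."""
    if reference not in summary.index:
        raise ValueError(f"reference level {reference!r} not in summary")
    ref_mean = summary.loc[reference, "mean"]
    rows = {}
    for lv in summary.index:
        if lv in ("full", reference):
            continue
        diff = summary.loc[lv, "mean"] - ref_mean
        pct = 100.0 * diff / ref_mean if ref_mean != 0 else np.nan
        rows[lv] = {"dollar_diff": float(diff), "pct_diff": float(pct)}
    return pd.DataFrame(rows).T


def local_mean_smoother(k10, costs, bandwidth: float = 2.0,
                        grid=None) -> pd.DataFrame:
    """Nadaraya-Watson kernel-weighted local mean of cost over the K10 grid.

    Gaussian kernel with ``bandwidth`` in K10 units; the default grid is the
    integer scores 10..50.  Invariant to observation order.
    """
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    x = np.asarray(k10, dtype=float)
    y = np.asarray(costs, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct K10 values")
    if grid is None:
        grid = np.arange(10, 51)
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - x[None, :]) / bandwidth
    w = np.exp(-0.5 * z ** 2)
    fitted = (w @ y) / w.sum(axis=1)
    return pd.DataFrame({"k10": grid, "fitted": fitted})
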