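"""Selection-on-unobservables diagnostics in the coefficient-stability style.

Compares a baseline fit (exposure plus year dummies, and individual effects
under FE) with a fully controlled fit on the identical sample, then applies
the standard proportional-selection approximation:

    beta* = beta_tilde - delta (beta_dot - beta_tilde) (R_max - R_tilde)
                               / (R_tilde - R_dot)

where beta_dot/R_dot are the baseline effect and R-squared, beta_tilde /
R_tilde the controlled ones, R_max the hypothetical R-squared were all
relevant unobservables included, and delta the proportionality of selection
on unobservables relative to observables.  delta* solves beta* = 0.  The
full cubic estimator (which needs auxiliary variance and covariance moments)
is a documented extension point, not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .panel_estimators import DesignSpec, build_design, fit


@dataclass(frozen=True)
class OsterInputs:
    """Baseline/controlled effects with their R-squareds (same sample, same
    estimator, same R-squared definition)."""

    beta_dot: float
    r2_dot: float
    beta_tilde: float
    r2_tilde: float
    se_dot: float = np.nan
    se_tilde: float = np.nan
    n: int = 0

    def __post_init__(self) -> None:
        for name in ("r2_dot", "r2_tilde"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")


def beta_star(inputs: OsterInputs, r_max: float, delta: float = 1.0) -> float:
    """Bias-adjusted coefficient under proportional selection."""
    if inputs.r2_tilde <= inputs.r2_dot:
        raise ValueError("controls add no explanatory power (R_tilde <= R_dot)")
    if r_max < inputs.r2_tilde:
        raise ValueError("R_max must be at least the controlled R-squared")
    move = inputs.beta_dot - inputs.beta_tilde
    return inputs.beta_tilde - delta * move * (r_max - inputs.r2_tilde) \
        / (inputs.r2_tilde - inputs.r2_dot)


def delta_for_zero(inputs: OsterInputs, r_max: float) -> float:
    """Proportionality delta* at which the bias-adjusted coefficient is zero.

    Undefined (infinite) when baseline and controlled effects coincide; that
    case returns +/-inf with the sign of beta_tilde.
    """
    if r_max <= inputs.r2_tilde:
        raise ValueError("R_max must exceed the controlled R-squared")
    move = inputs.beta_dot - inputs.beta_tilde
    if move == 0:
        return float(np.inf) if inputs.beta_tilde >= 0 else float(-np.inf)
    return inputs.beta_tilde * (inputs.r2_tilde - inputs.r2_dot) \
        / (move * (r_max - inputs.r2_tilde))


def rmax_grid(r2_tilde: float, multipliers=(1.3, 2.2)) -> list:
    """R_max candidates: multiplier x controlled R-squared, capped at 1."""
    if any(m < 1 for m in multipliers):
        raise ValueError("R_max multipliers must be >= 1")
    return [min(m * r2_tilde, 1.0) for m in multipliers]


def fit_baseline_controlled(panel: pd.DataFrame, costs: pd.DataFrame,
                            spec: DesignSpec) -> OsterInputs:
    """Baseline (exposure-only) and controlled fits on the identical sample.

    The baseline keeps the exposure, year dummies and (under FE) individual
    effects; the controlled fit adds the full control set.  Both fits are run
    on the intersection of complete cases so the R-squared movement is not a
    sample-composition artifact, and both use the same R-squared definition
    (within R-squared for FE, overall otherwise).
    """
    spec_ctrl = spec
    spec_base = _dc_replace(spec, controls=())
    d_ctrl = build_design(panel, costs, spec_ctrl)
    d_base = build_design(panel, costs, spec_base)
    common = d_ctrl.row_index.intersection(d_base.row_index)
    if len(common) < len(d_ctrl.row_index) or len(common) < len(d_base.row_index):
        keep_c = d_ctrl.row_index.isin(common)
        keep_b = d_base.row_index.isin(common)
        d_ctrl = _subset_design(d_ctrl, keep_c)
        d_base = _subset_design(d_base, keep_b)
    f_ctrl = fit(d_ctrl)
    f_base = fit(d_base)
    expo = d_ctrl.exposure_cols[0]
    return OsterInputs(
        beta_dot=float(f_base.params[expo]), r2_dot=float(f_base.r2),
        beta_tilde=float(f_ctrl.params[expo]), r2_tilde=float(f_ctrl.r2),
        se_dot=float(f_base.se[expo]), se_tilde=float(f_ctrl.se[expo]),
        n=f_ctrl.n,
    )


def _subset_design(design, keep: np.ndarray):
    import pandas as pd
    from dataclasses import replace
    ids, codes = np.unique(design.cluster_labels[design.clusters[keep]],
                           return_inverse=True)
    return replace(design, y=design.y[keep], X=design.X[keep],
                   clusters=codes, cluster_labels=ids,
                   row_index=design.row_index[keep],
                   k10=design.k10[keep])


def oster_table(inputs: OsterInputs, multipliers=(1.3, 2.2),
                delta: float = 1.0) -> pd.DataFrame:
    """One row per R_max: delta* for beta=0 and beta* at the given delta."""
    rows = []
    for m, r_max in zip(multipliers, rmax_grid(inputs.r2_tilde, multipliers)):
        rows.append({
            "rmax_multiplier": m,
            "r_max": r_max,
            "beta_dot": inputs.beta_dot,
            "r2_dot": inputs.r2_dot,
            "beta_tilde": inputs.beta_tilde,
            "r2_tilde": inputs.r2_tilde,
            "delta_star": delta_for_zero(inputs, r_max)
            if r_max > inputs.r2_tilde else np.nan,
            "beta_star": beta_star(inputs, r_max, delta),
        })
    return pd.DataFrame(rows)
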