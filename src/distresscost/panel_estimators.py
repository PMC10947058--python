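"""Linear panel estimators: within (FE), Swamy-Arora random effects, pooled OLS.

Everything is computed directly from the design arrays so each estimator can
be checked against an independent oracle (e.g. FE against dummy-variable
least squares).  Cluster-robust "sandwich" variances are clustered on the
woman identifier with the usual small-sample scaling
G/(G-1) x (N-1)/(N-K).

The design builder turns a merged panel + annual-cost table into response /
regressor arrays: categorical covariates are expanded against declared
reference levels, year dummies are always included, log-cost outcomes are
restricted to positive-cost rows, and incomplete rows are listwise deleted
(with a count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .distress_coding import DEFAULT_CUTOFFS, DistressCutoffs, k10_levels, distress_dummy

DEFAULT_CONTROLS = ["age", "marital", "education", "unemployed", "income_mgmt",
                    "healthcare_card", "residence", "state"]
CATEGORICAL_CONTROLS = {"marital", "education", "residence", "state"}

_WITHIN_TOL = 1e-10


@dataclass(frozen=True)
class DesignSpec:
    """What to regress on what, and how.

    ``outcome`` is either ``positive_<col>`` (any-spending indicator),
    ``log_<col>`` (natural log of a positive cost column) or a raw column
    name.  ``exposure`` is one of ``k10``, ``distress_dummy``,
    ``level_dummies`` or the name of a binary column already on the panel.
    """

    outcome: str = "log_total"
    exposure: str = "k10"
    controls: tuple = tuple(DEFAULT_CONTROLS)
    estimator: str = "FE"           # FE | RE | OLS
    cluster: str = "id"
    include_year_dummies: bool = True
    cutoffs: DistressCutoffs = DEFAULT_CUTOFFS

    def __post_init__(self) -> None:
        if self.estimator not in ("FE", "RE", "OLS"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.exposure in self.controls:
            raise ValueError("exposure must not appear in the control set")


@dataclass
class Design:
    """Materialised regression problem (one row per usable woman-wave)."""

    y: np.ndarray
    X: np.ndarray
    columns: list
    clusters: np.ndarray            # integer codes, one per row
    cluster_labels: np.ndarray      # original woman ids, one per code
    row_index: pd.MultiIndex        # (id, wave) of retained rows
    exposure_cols: list
    k10: np.ndarray                 # realized K10 per row (for smearing groups)
    spec: DesignSpec
    n_dropped_missing: int = 0
    dropped_columns: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)


@dataclass
class FitResult:
    """Coefficients with cluster-robust variance and fit diagnostics."""

    params: pd.Series
    vcov: pd.DataFrame
    se: pd.Series
    n: int
    n_clusters: int
    r2: float
    estimator: str
    resid: np.ndarray = field(repr=False, default=None)
    individual_effects: pd.Series = field(repr=False, default=None)  # FE only
    variance_components: dict = None                                 # RE only
    df_resid: int = 0
    dropped_columns: list = field(default_factory=list)

    def tidy(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE, t, p (normal reference)."""
        from scipy import stats
        t = self.params / self.se
        p = 2 * stats.norm.sf(np.abs(t))
        return pd.DataFrame({"estimate": self.params, "se": self.se,
                             "t": t, "p": p})


def _expand_exposure(df: pd.DataFrame, spec: DesignSpec) -> tuple[pd.DataFrame, list]:
    if spec.exposure == "k10":
        return df[["k10"]].astype(float), ["k10"]
    if spec.exposure == "distress_dummy":
        col = distress_dummy(df["k10"].to_numpy(), spec.cutoffs)
        return pd.DataFrame({"distress_dummy": col.astype(float)}, index=df.index), \
            ["distress_dummy"]
    if spec.exposure == "level_dummies":
        lv = k10_levels(df["k10"].to_numpy(), spec.cutoffs)
        out = pd.DataFrame(index=df.index)
        for name in ("mild", "moderate", "severe"):
            out[f"level_{name}"] = (lv == name).astype(float)
        return out, list(out.columns)
    # custom binary/continuous exposure column
    if spec.exposure not in df.columns:
        raise ValueError(f"exposure column {spec.exposure!r} not found")
    return df[[spec.exposure]].astype(float), [spec.exposure]


def _expand_controls(df: pd.DataFrame, controls) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for c in controls:
        if c not in df.columns:
            raise ValueError(f"control column {c!r} not found")
        if c in CATEGORICAL_CONTROLS or df[c].dtype == object:
            levels = sorted(pd.unique(df[c].astype(str)))
            for lev in levels[1:]:  # first (sorted) level is the reference
                out[f"{c}[{lev}]"] = (df[c].astype(str) == lev).astype(float)
        else:
            out[c] = df[c].astype(float)
    return out


def build_design(panel: pd.DataFrame, costs: pd.DataFrame, spec: DesignSpec) -> Design:
    """Join panel and costs and materialise (y, X, clusters) for ``spec``."""
    df = panel.merge(costs, on=["id", "wave"], how="inner",
                     suffixes=("", "_cost"))
    n0 = len(df)

    if spec.outcome.startswith("positive_"):
        base = spec.outcome[len("positive_"):]
        y_raw = (df[base] > 0).astype(float) if spec.outcome not in df else \
            df[spec.outcome].astype(float)
        keep = pd.Series(True, index=df.index)
    elif spec.outcome.startswith("log_"):
        base = spec.outcome[len("log_"):]
        keep = df[base] > 0
        y_raw = pd.Series(np.nan, index=df.index)
        y_raw[keep] = np.log(df.loc[keep, base].astype(float))
    else:
        y_raw = df[spec.outcome].astype(float)
        keep = pd.Series(True, index=df.index)

    expo, expo_cols = _expand_exposure(df, spec)
    ctrl = _expand_controls(df, spec.controls)
    parts = [expo, ctrl]
    if spec.include_year_dummies:
        years = sorted(df["year"].unique())
        yd = pd.DataFrame(index=df.index)
        for yv in years[1:]:
            yd[f"year[{yv}]"] = (df["year"] == yv).astype(float)
        parts.append(yd)
    X = pd.concat(parts, axis=1)

    complete = keep & y_raw.notna() & X.notna().all(axis=1)
    n_dropped = int(n0 - complete.sum())
    if complete.sum() == 0:
        raise ValueError("all rows deleted while building the design")
    df, X, y_raw = df[complete], X[complete], y_raw[complete]

    # drop zero-variance regressors (after outcome restriction)
    dropped = [c for c in X.columns if float(np.var(X[c].to_numpy())) <= _WITHIN_TOL]
    if dropped:
        warnings.warn(f"dropping zero-variance regressor(s): {dropped}")
        X = X.drop(columns=dropped)
    expo_cols = [c for c in expo_cols if c in X.columns]
    if not expo_cols:
        raise ValueError("exposure has no variance after restriction")

    ids, codes = np.unique(df[spec.cluster].to_numpy(), return_inverse=True)
    return Design(
        y=y_raw.to_numpy(dtype=float),
        X=X.to_numpy(dtype=float),
        columns=list(X.columns),
        clusters=codes,
        cluster_labels=ids,
        row_index=pd.MultiIndex.from_frame(df[["id", "wave"]]),
        exposure_cols=expo_cols,
        k10=df["k10"].to_numpy(),
        spec=spec,
        n_dropped_missing=n_dropped,
        dropped_columns=dropped,
    )


# ---------------------------------------------------------------------------
# core linear algebra


def group_means(M: np.ndarray, groups: np.ndarray, n_groups: int) -> np.ndarray:
    """Per-group column means of M (rows grouped by integer codes)."""
    counts = np.bincount(groups, minlength=n_groups).astype(float)
    if M.ndim == 1:
        sums = np.bincount(groups, weights=M, minlength=n_groups)
        return sums / counts
    sums = np.zeros((n_groups, M.shape[1]))
    for j in range(M.shape[1]):
        sums[:, j] = np.bincount(groups, weights=M[:, j], minlength=n_groups)
    return sums / counts[:, None]


def within_transform(M: np.ndarray, groups: np.ndarray, n_groups: int) -> np.ndarray:
    """Subtract each group's mean from its rows (the within/demeaning operator)."""
    return M - group_means(M, groups, n_groups)[groups]


def cluster_robust_vcov(X: np.ndarray, resid: np.ndarray, clusters: np.ndarray,
                        n_params_absorbed: int = 0) -> np.ndarray:
    """Cluster-robust sandwich variance with small-sample scaling.

    ``n_params_absorbed`` counts parameters swept out before estimation (the
    G individual effects for the within estimator); they enter the N-K
    degrees-of-freedom scaling.
    """
    n, k = X.shape
    labels = np.unique(clusters)
    g = len(labels)
    if g < 2:
        raise ValueError("cluster-robust variance requires at least 2 clusters")
    xtx_inv = np.linalg.pinv(X.T @ X)
    scores = np.zeros((g, k))
    xe = X * resid[:, None]
    codes = np.searchsorted(labels, clusters)
    for j in range(k):
        scores[:, j] = np.bincount(codes, weights=xe[:, j], minlength=g)
    meat = scores.T @ scores
    k_total = k + n_params_absorbed
    scale = (g / (g - 1)) * ((n - 1) / max(n - k_total, 1))
    return scale * xtx_inv @ meat @ xtx_inv


def _finish(design: Design, beta: np.ndarray, resid: np.ndarray, Xv: np.ndarray,
            r2: float, estimator: str, absorbed: int = 0,
            individual_effects: pd.Series = None,
            variance_components: dict = None) -> FitResult:
    if design.n_clusters >= 2:
        V = cluster_robust_vcov(Xv, resid, design.clusters, n_params_absorbed=absorbed)
    else:
        warnings.warn("single cluster: cluster-robust variance undefined (NaN)")
        V = np.full((Xv.shape[1], Xv.shape[1]), np.nan)
    params = pd.Series(beta, index=design.columns if len(beta) == len(design.columns)
                       else list(design.columns) + ["const"])
    cols = list(params.index)
    return FitResult(
        params=params,
        vcov=pd.DataFrame(V, index=cols, columns=cols),
        se=pd.Series(np.sqrt(np.diag(V)), index=cols),
        n=design.n, n_clusters=design.n_clusters, r2=r2, estimator=estimator,
        resid=resid, individual_effects=individual_effects,
        variance_components=variance_components,
        df_resid=design.n - len(beta) - absorbed,
        dropped_columns=list(design.dropped_columns),
    )


def fit_within(design: Design) -> FitResult:
    """Within (fixed-effects) estimator: OLS on individually demeaned data.

    Time-invariant columns are detected after demeaning and dropped with a
    warning; the estimated individual effects are recovered as
    ybar_i - xbar_i' beta.
    """
    g, ng = design.clusters, design.n_clusters
    yw = within_transform(design.y, g, ng)
    Xw = within_transform(design.X, g, ng)
    within_var = np.einsum("ij,ij->j", Xw, Xw) / max(design.n - 1, 1)
    keep = within_var > _WITHIN_TOL
    dropped = [c for c, k in zip(design.columns, keep) if not k]
    for c in design.exposure_cols:
        if c in dropped:
            raise ValueError(f"exposure {c!r} has no within-individual variation")
    if dropped:
        warnings.warn(f"dropping time-invariant regressor(s) under FE: {dropped}")
        design = replace(design, X=design.X[:, keep],
                         columns=[c for c in design.columns if c not in dropped],
                         dropped_columns=design.dropped_columns + dropped)
        Xw = Xw[:, keep]
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    ss_tot = float(yw @ yw)
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    alpha = group_means(design.y - design.X @ beta, g, ng)
    effects = pd.Series(alpha, index=design.cluster_labels)
    return _finish(design, beta, resid, Xw, r2, "FE", absorbed=ng,
                   individual_effects=effects)


def fit_pooled_ols(design: Design) -> FitResult:
    """Pooled OLS with an intercept and cluster-robust variance."""
    Xc = np.column_stack([design.X, np.ones(design.n)])
    beta, *_ = np.linalg.lstsq(Xc, design.y, rcond=None)
    resid = design.y - Xc @ beta
    yc = design.y - design.y.mean()
    ss_tot = float(yc @ yc)
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    return _finish(design, beta, resid, Xc, r2, "OLS")


def fit_random_effects(design: Design) -> FitResult:
    """Swamy-Arora random effects via feasible-GLS quasi-demeaning.

    Variance components: sigma2_e from the within residual sum of squares
    (df N - G - K_w); sigma2_u from the between regression on group means,
    subtracting sigma2_e weighted by the mean inverse group size, truncated
    at zero (in which case RE collapses to pooled OLS, with a warning).
    Each woman's demeaning weight is
    theta_i = 1 - sqrt(sigma2_e / (sigma2_e + T_i sigma2_u)).
    """
    g, ng = design.clusters, design.n_clusters
    T_i = np.bincount(g, minlength=ng).astype(float)

    # within step for sigma2_e
    yw = within_transform(design.y, g, ng)
    Xw = within_transform(design.X, g, ng)
    within_var = np.einsum("ij,ij->j", Xw, Xw) / max(design.n - 1, 1)
    kw = within_var > _WITHIN_TOL
    beta_w, *_ = np.linalg.lstsq(Xw[:, kw], yw, rcond=None)
    rw = yw - Xw[:, kw] @ beta_w
    df_e = max(design.n - ng - int(kw.sum()), 1)
    sigma2_e = float(rw @ rw) / df_e

    # between step for sigma2_u
    yb = group_means(design.y, g, ng)
    Xb = np.column_stack([group_means(design.X, g, ng), np.ones(ng)])
    beta_b, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
    rb = yb - Xb @ beta_b
    df_b = max(ng - Xb.shape[1], 1)
    sigma2_between = float(rb @ rb) / df_b
    sigma2_u = sigma2_between - sigma2_e * float(np.mean(1.0 / T_i))
    if sigma2_u < 0:
        warnings.warn("estimated individual variance component negative; "
                      "truncated to 0 (RE equals pooled OLS)")
        sigma2_u = 0.0

    theta = 1.0 - np.sqrt(sigma2_e / (sigma2_e + T_i * sigma2_u))
    ybar = group_means(design.y, g, ng)
    Xbar = group_means(design.X, g, ng)
    ystar = design.y - theta[g] * ybar[g]
    Xstar = design.X - theta[g][:, None] * Xbar[g]
    const = 1.0 - theta[g]
    Xs = np.column_stack([Xstar, const])
    beta, *_ = np.linalg.lstsq(Xs, ystar, rcond=None)
    resid = ystar - Xs @ beta
    # overall R^2 on the original scale
    fitted = np.column_stack([design.X, np.ones(design.n)]) @ beta
    yc = design.y - design.y.mean()
    ss_tot = float(yc @ yc)
    r2 = 1.0 - float(np.sum((design.y - fitted) ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return _finish(design, beta, resid, Xs, r2, "RE",
                   variance_components={"sigma2_e": sigma2_e, "sigma2_u": sigma2_u,
                                        "theta_range": (float(theta.min()),
                                                        float(theta.max()))})


def fit(design: Design) -> FitResult:
    """Dispatch on the spec's estimator."""
    return {"FE": fit_within, "RE": fit_random_effects,
            "OLS": fit_pooled_ols}[design.spec.estimator](design)
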