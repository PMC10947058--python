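"""Two-part healthcare cost model: extensive + intensive margins, Duan
smearing retransformation, and bootstrapped incremental dollar effects.

Part 1 is a linear probability model for incurring any cost; part 2 is a
linear model for log cost on the positive-cost rows.  Both parts share the
estimator (FE / RE / OLS), control set and clustering.  Predictions on the
dollar scale multiply the clipped part-1 probability by exp(part-2 linear
predictor) times a Duan smearing factor -- the mean of exponentiated part-2
residuals -- estimated separately by distress group to respect the
heteroskedasticity of costs across distress levels.

Incremental effects contrast two counterfactual exposure states (e.g. K10
s -> s+1, distress dummy 0 -> 1, level none -> severe), averaging the
per-row predicted difference over the estimation sample.  Standard errors
come from a cluster bootstrap that resamples whole women and re-runs the
entire two-part pipeline, smearing included, in every replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .distress_coding import DistressCutoffs, k10_level
from .panel_estimators import (Design, DesignSpec, FitResult, build_design, fit,
                               group_means, within_transform)


@dataclass
class SmearingTable:
    """Duan smearing factors by group: factor_g = mean over g of exp(residual)."""

    factors: dict
    sizes: dict

    @property
    def overall(self) -> float:
        """Size-weighted mean of the group factors (equals the pooled factor)."""
        n = sum(self.sizes.values())
        return sum(self.factors[g] * self.sizes[g] for g in self.factors) / n

    def lookup(self, group) -> float:
        if group in self.factors:
            return self.factors[group]
        warnings.warn(f"no smearing factor for group {group!r}; using overall factor")
        return self.overall


def duan_smearing(residuals: np.ndarray, groups) -> SmearingTable:
    """Smearing factors from log-scale residuals, one per group label."""
    residuals = np.asarray(residuals, dtype=float)
    groups = np.asarray(groups)
    if len(residuals) != len(groups):
        raise ValueError("residuals and group labels differ in length")
    factors, sizes = {}, {}
    for g in pd.unique(groups):
        m = groups == g
        if not m.any():
            continue
        factors[g] = float(np.mean(np.exp(residuals[m])))
        sizes[g] = int(m.sum())
    if not factors:
        raise ValueError("no non-empty smearing group")
    return SmearingTable(factors=factors, sizes=sizes)


@dataclass
class TwoPartFit:
    """Paired extensive/intensive fits with smearing factors and designs."""

    part1: FitResult
    part2: FitResult
    smearing: SmearingTable
    design1: Design = field(repr=False, default=None)
    design2: Design = field(repr=False, default=None)
    spec: DesignSpec = None
    smearing_grouping: str = "level"


@dataclass
class EffectResult:
    """Dollar-scale effect of an exposure contrast, with bootstrap uncertainty."""

    exposure: str
    contrast: tuple
    conditional: float
    unconditional: float
    log_coef: float = np.nan
    conditional_se: float = np.nan
    unconditional_se: float = np.nan
    conditional_ci: tuple = None
    unconditional_ci: tuple = None
    B: int = 0
    seed: int = None
    n_failed: int = 0


def _group_labels(exposure: str, k10: np.ndarray, expo_values: np.ndarray,
                  cutoffs: DistressCutoffs, grouping: str) -> np.ndarray:
    """Smearing group label per row, from the realized exposure."""
    if exposure == "k10" and grouping == "score":
        return k10.astype(int).astype(str)
    if exposure in ("k10", "level_dummies"):
        from .distress_coding import k10_levels
        return k10_levels(k10, cutoffs)
    return expo_values.astype(int).astype(str)  # binary exposures: groups "0"/"1"


def _counterfactual_group(exposure: str, value, cutoffs: DistressCutoffs,
                          grouping: str):
    if exposure == "k10":
        return str(int(value)) if grouping == "score" else k10_level(int(round(value)), cutoffs)
    if exposure == "level_dummies":
        return value
    return str(int(value))


def _counterfactual_X(X: np.ndarray, columns: list, exposure: str, value) -> np.ndarray:
    """Copy of X with the exposure column(s) set to the counterfactual value."""
    Xc = X.copy()
    col = {c: i for i, c in enumerate(columns)}
    if exposure == "level_dummies":
        for name in ("mild", "moderate", "severe"):
            c = f"level_{name}"
            if c in col:
                Xc[:, col[c]] = 1.0 if value == name else 0.0
        return Xc
    name = "distress_dummy" if exposure == "distress_dummy" else exposure
    if name not in col:
        raise ValueError(f"exposure column {name!r} not in design")
    Xc[:, col[name]] = float(value)
    return Xc


def fit_two_part(panel: pd.DataFrame, costs: pd.DataFrame, spec: DesignSpec,
                 smearing_grouping: str = "level") -> TwoPartFit:
    """Fit both parts of the two-part model for a raw cost column.

    ``spec.outcome`` names the cost column (e.g. ``total``); the parts use
    ``positive_<outcome>`` and ``log_<outcome>``.
    """
    base = spec.outcome
    if base.startswith(("positive_", "log_")):
        raise ValueError("fit_two_part expects the raw cost column name as outcome")
    spec1 = replace(spec, outcome=f"positive_{base}")
    spec2 = replace(spec, outcome=f"log_{base}")
    design1 = build_design(panel, costs, spec1)
    if design1.y.std() == 0:
        warnings.warn("positivity outcome is constant; part-1 coefficients are degenerate")
    design2 = build_design(panel, costs, spec2)
    if design2.n == 0:
        raise ValueError("positive-cost subsample is empty")
    fit1 = fit(design1)
    fit2 = fit(design2)
    expo2 = design2.X[:, design2.columns.index(design2.exposure_cols[0])] \
        if design2.exposure_cols[0] in design2.columns else None
    groups = _group_labels(spec.exposure, design2.k10, expo2,
                           spec.cutoffs, smearing_grouping)
    # smearing uses prediction-scale residuals: y - lp, where lp is exactly the
    # linear predictor later used for dollar-scale predictions (incl. the
    # individual effects for FE, the Xb + const prediction for RE/OLS)
    resid_sm = design2.y - _linear_predictor(design2, fit2)
    smear = duan_smearing(resid_sm, groups)
    return TwoPartFit(part1=fit1, part2=fit2, smearing=smear,
                      design1=design1, design2=design2, spec=spec,
                      smearing_grouping=smearing_grouping)


def _align_X(design_from: Design, fit_to: FitResult) -> np.ndarray:
    """Columns of ``design_from.X`` reordered to match ``fit_to``'s parameters.

    FE fits may have dropped time-invariant columns (absorbed by the
    individual effects); OLS/RE fits carry a trailing constant.
    """
    names = [c for c in fit_to.params.index if c != "const"]
    idx = [design_from.columns.index(c) for c in names]
    X = design_from.X[:, idx]
    if "const" in fit_to.params.index:
        X = np.column_stack([X, np.ones(len(X))])
    return X


def _linear_predictor(design_rows: Design, fitres: FitResult,
                      X_override: np.ndarray = None) -> np.ndarray:
    """Linear prediction over ``design_rows`` including estimated individual
    effects for FE fits (women unseen by the fit get the mean effect)."""
    names = [c for c in fitres.params.index if c != "const"]
    if X_override is None:
        X = _align_X(design_rows, fitres)
    else:
        idx = [design_rows.columns.index(c) for c in names]
        X = X_override[:, idx]
        if "const" in fitres.params.index:
            X = np.column_stack([X, np.ones(len(X))])
    lp = X @ fitres.params.to_numpy()
    if fitres.individual_effects is not None:
        eff = fitres.individual_effects.reindex(
            design_rows.cluster_labels[design_rows.clusters])
        filled = eff.fillna(fitres.individual_effects.mean()).to_numpy()
        lp = lp + filled
    return lp


def predict_unconditional(tpf: TwoPartFit, exposure_value=None) -> np.ndarray:
    """Per-row predicted dollars over the part-1 estimation sample.

    clip(part-1 prediction, 0, 1) x exp(part-2 linear predictor) x smearing
    factor of the row's (possibly counterfactual) distress group.
    """
    d1 = tpf.design1
    if exposure_value is None:
        X_cf = None
        groups = _group_labels(tpf.spec.exposure, d1.k10,
                               d1.X[:, d1.columns.index(d1.exposure_cols[0])],
                               tpf.spec.cutoffs, tpf.smearing_grouping)
        s = np.array([tpf.smearing.lookup(g) for g in groups])
    else:
        X_cf = _counterfactual_X(d1.X, d1.columns, tpf.spec.exposure, exposure_value)
        g = _counterfactual_group(tpf.spec.exposure, exposure_value,
                                  tpf.spec.cutoffs, tpf.smearing_grouping)
        s = tpf.smearing.lookup(g)
    p = np.clip(_linear_predictor(d1, tpf.part1, X_cf), 0.0, 1.0)
    lp2 = _linear_predictor(d1, tpf.part2, X_cf if X_cf is not None else d1.X)
    return p * np.exp(lp2) * s


def incremental_effect(tpf: TwoPartFit, contrast: tuple) -> EffectResult:
    """Point estimates of the conditional and unconditional dollar effects.

    ``contrast=(a, b)`` are counterfactual exposure values; the effect is the
    sample mean of the per-row predicted difference b minus a.  For K10 the
    one-unit "marginal" effect uses the finite difference (s, s+1).
    """
    a, b = contrast
    if a == b:
        warnings.warn("contrast endpoints are equal; effect is exactly zero")
        return EffectResult(tpf.spec.exposure, contrast, 0.0, 0.0, 0.0)
    d1 = tpf.design1
    out = {}
    for tag, v in (("a", a), ("b", b)):
        X_cf = _counterfactual_X(d1.X, d1.columns, tpf.spec.exposure, v)
        g = _counterfactual_group(tpf.spec.exposure, v, tpf.spec.cutoffs,
                                  tpf.smearing_grouping)
        s = tpf.smearing.lookup(g)
        p = np.clip(_linear_predictor(d1, tpf.part1, X_cf), 0.0, 1.0)
        lp2 = _linear_predictor(d1, tpf.part2, X_cf)
        out[tag] = {"cond": np.exp(lp2) * s, "uncond": p * np.exp(lp2) * s}
    conditional = float(np.mean(out["b"]["cond"] - out["a"]["cond"]))
    unconditional = float(np.mean(out["b"]["uncond"] - out["a"]["uncond"]))
    log_coef = _log_scale_contrast(tpf, a, b)
    return EffectResult(tpf.spec.exposure, contrast, conditional, unconditional,
                        log_coef=log_coef)


def _log_scale_contrast(tpf: TwoPartFit, a, b) -> float:
    """Part-2 log-scale contrast implied by the exposure coefficients."""
    params = tpf.part2.params
    if tpf.spec.exposure == "level_dummies":
        def lv(v):
            return 0.0 if v == "none" else float(params.get(f"level_{v}", np.nan))
        return lv(b) - lv(a)
    name = "distress_dummy" if tpf.spec.exposure == "distress_dummy" else tpf.spec.exposure
    return float(params.get(name, np.nan)) * (float(b) - float(a))


# ---------------------------------------------------------------------------
# cluster bootstrap
#
# The replicate loop re-runs the entire two-part pipeline on resampled women.
# It works on the design arrays built once from the data (the design build is
# deterministic row-wise, so resampling rows of the built arrays is identical
# to rebuilding from the resampled tables) and treats every resampled copy of
# a woman as a distinct cluster.


class _BootState:
    """Pre-built arrays for fast pipeline re-runs on resampled clusters."""

    def __init__(self, tpf: TwoPartFit, contrast: tuple):
        d1, spec = tpf.design1, tpf.spec
        self.estimator = spec.estimator
        self.y1 = d1.y
        self.clusters = d1.clusters
        self.n_clusters = d1.n_clusters
        self.X = d1.X
        self.columns = d1.columns
        a, b = contrast
        self.Xa = _counterfactual_X(d1.X, d1.columns, spec.exposure, a)
        self.Xb = _counterfactual_X(d1.X, d1.columns, spec.exposure, b)
        self.group_a = _counterfactual_group(spec.exposure, a, spec.cutoffs,
                                             tpf.smearing_grouping)
        self.group_b = _counterfactual_group(spec.exposure, b, spec.cutoffs,
                                             tpf.smearing_grouping)
        # log outcome aligned on part-1 rows (NaN where cost is zero)
        pos_index = set(map(tuple, tpf.design2.row_index))
        mask = np.array([t in pos_index for t in map(tuple, d1.row_index)])
        self.pos = mask
        self.y2 = np.full(d1.n, np.nan)
        self.y2[mask] = tpf.design2.y
        expo1 = d1.X[:, d1.columns.index(d1.exposure_cols[0])]
        self.fit_groups = _group_labels(spec.exposure, d1.k10, expo1,
                                        spec.cutoffs, tpf.smearing_grouping)
        # map group labels to codes for bincount-based smearing
        self.group_codes, self.group_index = pd.factorize(self.fit_groups)
        self.code_a = int(np.where(self.group_index == self.group_a)[0][0]) \
            if self.group_a in self.group_index else -1
        self.code_b = int(np.where(self.group_index == self.group_b)[0][0]) \
            if self.group_b in self.group_index else -1
        # per-cluster row slices for resampling
        order = np.argsort(self.clusters, kind="stable")
        self.rows_by_cluster = np.split(order, np.cumsum(
            np.bincount(self.clusters, minlength=self.n_clusters))[:-1])

    def point(self, rows: np.ndarray, new_clusters: np.ndarray) -> tuple:
        """(conditional, unconditional) effects on one (re)sample."""
        est = self.estimator
        ng = new_clusters.max() + 1
        y1, X = self.y1[rows], self.X[rows]
        Xa, Xb = self.Xa[rows], self.Xb[rows]
        if est == "FE":
            b1, a1 = _fe_solve(y1, X, new_clusters, ng)
            p_a = np.clip(Xa @ b1 + a1[new_clusters], 0, 1)
            p_b = np.clip(Xb @ b1 + a1[new_clusters], 0, 1)
        else:
            b1 = _re_solve(y1, X, new_clusters, ng) if est == "RE" else _ols_solve(y1, X)
            p_a = np.clip(_with_const(Xa) @ b1, 0, 1)
            p_b = np.clip(_with_const(Xb) @ b1, 0, 1)
        pos = self.pos[rows]
        if not pos.any():
            raise RuntimeError("replicate has an empty positive-cost subsample")
        y2 = self.y2[rows][pos]
        X2, cl2 = X[pos], new_clusters[pos]
        if est == "FE":
            # relabel part-2 clusters densely for bincount
            u, cl2d = np.unique(cl2, return_inverse=True)
            b2, a2 = _fe_solve(y2, X2, cl2d, len(u))
            alpha_full = np.full(ng, np.nan)
            alpha_full[u] = a2
            missing = np.isnan(alpha_full)
            if missing.any():
                alpha_full[missing] = np.nanmean(a2)
            resid2 = y2 - X2 @ b2 - a2[cl2d]
            lp2_a = Xa @ b2 + alpha_full[new_clusters]
            lp2_b = Xb @ b2 + alpha_full[new_clusters]
        else:
            u2, cl2d = np.unique(cl2, return_inverse=True)
            b2 = _re_solve(y2, X2, cl2d, len(u2)) if est == "RE" else _ols_solve(y2, X2)
            resid2 = y2 - _with_const(X2) @ b2
            lp2_a = _with_const(Xa) @ b2
            lp2_b = _with_const(Xb) @ b2
        # smearing by group on the replicate's own part-2 residuals
        gc = self.group_codes[rows][pos]
        k = len(self.group_index)
        sums = np.bincount(gc, weights=np.exp(resid2), minlength=k)
        counts = np.bincount(gc, minlength=k)
        overall = sums.sum() / counts.sum()
        with np.errstate(invalid="ignore"):
            factors = np.where(counts > 0, sums / np.maximum(counts, 1), overall)
        s_a = factors[self.code_a] if self.code_a >= 0 else overall
        s_b = factors[self.code_b] if self.code_b >= 0 else overall
        cond = float(np.mean(np.exp(lp2_b) * s_b - np.exp(lp2_a) * s_a))
        uncond = float(np.mean(p_b * np.exp(lp2_b) * s_b - p_a * np.exp(lp2_a) * s_a))
        return cond, uncond


def _with_const(X: np.ndarray) -> np.ndarray:
    return np.column_stack([X, np.ones(len(X))])


def _ols_solve(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(_with_const(X), y, rcond=None)
    return beta


def _fe_solve(y: np.ndarray, X: np.ndarray, clusters: np.ndarray, ng: int) -> tuple:
    yw = within_transform(y, clusters, ng)
    Xw = within_transform(X, clusters, ng)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    alpha = group_means(y - X @ beta, clusters, ng)
    return beta, alpha


def _re_solve(y: np.ndarray, X: np.ndarray, clusters: np.ndarray, ng: int) -> np.ndarray:
    """Swamy-Arora quasi-demeaned GLS; returns coefficients with const last."""
    n, k = X.shape
    T_i = np.bincount(clusters, minlength=ng).astype(float)
    yw = within_transform(y, clusters, ng)
    Xw = within_transform(X, clusters, ng)
    bw, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    rw = yw - Xw @ bw
    rank_w = int((np.einsum("ij,ij->j", Xw, Xw) > 1e-10).sum())
    sigma2_e = float(rw @ rw) / max(n - ng - rank_w, 1)
    yb = group_means(y, clusters, ng)
    Xb = _with_const(group_means(X, clusters, ng))
    bb, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
    rb = yb - Xb @ bb
    sigma2_u = max(float(rb @ rb) / max(ng - Xb.shape[1], 1)
                   - sigma2_e * float(np.mean(1.0 / T_i)), 0.0)
    theta = 1.0 - np.sqrt(sigma2_e / (sigma2_e + T_i * sigma2_u))
    ystar = y - theta[clusters] * yb[clusters]
    Xstar = X - theta[clusters][:, None] * group_means(X, clusters, ng)[clusters]
    Xs = np.column_stack([Xstar, 1.0 - theta[clusters]])
    beta, *_ = np.linalg.lstsq(Xs, ystar, rcond=None)
    return beta


def cluster_bootstrap(tpf: TwoPartFit, contrast: tuple, B: int = 200,
                      seed: int = 0, max_failure_frac: float = 0.1) -> EffectResult:
    """Bootstrap SEs/CIs for an incremental effect by resampling whole women.

    Each replicate draws ``n_clusters`` women with replacement (every copy a
    distinct cluster), re-runs both parts and the smearing, and recomputes
    the effects.  SE is the SD across replicates; the CI is percentile-based.
    Replicates that fail (e.g. empty positive subsample) are counted; more
    than ``max_failure_frac`` of them is an error.
    """
    if B < 2:
        raise ValueError("bootstrap requires B >= 2")
    if tpf.design1.n_clusters < 2:
        raise ValueError("bootstrap requires at least 2 clusters")
    point = incremental_effect(tpf, contrast)
    state = _BootState(tpf, contrast)
    rng = np.random.default_rng(seed)
    cond, uncond = [], []
    n_failed = 0
    ng = state.n_clusters
    for _ in range(B):
        draw = rng.integers(0, ng, size=ng)
        rows = np.concatenate([state.rows_by_cluster[i] for i in draw])
        sizes = np.array([len(state.rows_by_cluster[i]) for i in draw])
        new_clusters = np.repeat(np.arange(ng), sizes)
        try:
            c, u = state.point(rows, new_clusters)
            cond.append(c)
            uncond.append(u)
        except (RuntimeError, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed > max_failure_frac * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed")
    cond, uncond = np.asarray(cond), np.asarray(uncond)
    return replace(
        point,
        conditional_se=float(np.std(cond, ddof=1)),
        unconditional_se=float(np.std(uncond, ddof=1)),
        conditional_ci=(float(np.percentile(cond, 2.5)),
                        float(np.percentile(cond, 97.5))),
        unconditional_ci=(float(np.percentile(uncond, 2.5)),
                          float(np.percentile(uncond, 97.5))),
        B=B, seed=seed, n_failed=n_failed,
    )
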