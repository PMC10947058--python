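"""Synthetic panel + claims generator with known ground truth.

Emulates the structure of an annual women's-health survey panel linked to
administrative claims: ~5 annual waves of an unbalanced panel of young women
with a K10 distress score (integer 10-50, declining mean with age), ~97%
of woman-years with positive annual spending, right-skewed costs whose mean
and residual spread rise with distress, category shares in which allied and
specialist (mental-health) use rises steeply with K10, monthly claim timing,
and monotone attrition.

The data-generating process mirrors the estimation model so parameter
recovery is well defined:

* individual cost effect u_i ~ N(0, sigma_u^2), correlated (rho_selection)
  with the individual K10 propensity -- a positive correlation makes pooled
  estimators overstate the FE effect;
* K10 is a rounded, clipped latent AR(1)-plus-propensity process (within-
  woman variation identifies the within estimator);
* log positive cost = alpha + beta_k10 K10 + eta'X + u_i + year effect + eps,
  with eps SD set per distress level (heteroskedasticity);
* any-spending follows a logistic index in K10 whose intercept is calibrated
  so the zero-spending share matches ``zero_mass_target``.

Because positivity is logistic while estimation is a linear probability
model, true incremental effects are defined by contrasting DGP expectations
(the exact lognormal closed form averaged over the realized sample), not by
reading off coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .distress_coding import DEFAULT_CUTOFFS, k10_levels

MARITAL = ("never_married", "married", "defacto", "separated")
EDUCATION = ("year10", "year11", "year12", "certificate", "diploma", "degree", "postgrad")
RESIDENCE = ("metro", "regional", "rural")
STATES = ("NSW", "VIC", "QLD", "SA", "WA", "TAS", "NT", "ACT")

# fixed covariate effects on log cost (scaled by covariate_effects_scale)
_ETA = {"age": 0.01, "unemployed": 0.05, "income_mgmt": 0.08, "healthcare_card": 0.15}
# covariate effect on the positivity logit
_GAMMA_X = {"healthcare_card": 0.10}

DEFAULT_CATEGORY_SHARES = {
    "base": {"GP": 0.35, "specialist": 0.06, "specialist_psychiatry": 0.02,
             "allied": 0.04, "allied_mh": 0.04, "pathology": 0.12, "imaging": 0.05,
             "other": 0.12, "PBS_antidepressant": 0.04, "PBS_other": 0.16},
    # per-category exponential tilt in (K10-10)/40; positive = rises with distress
    "slope": {"specialist": 0.4, "specialist_psychiatry": 1.2, "allied": 0.6,
              "allied_mh": 1.4, "PBS_antidepressant": 1.2},
    "concentration": 4.0,
}

DEFAULT_OOP_FRACTION = {"GP": 0.10, "specialist": 0.35, "specialist_psychiatry": 0.40,
                        "allied": 0.30, "allied_mh": 0.35, "pathology": 0.05,
                        "imaging": 0.15, "other": 0.15,
                        "PBS_antidepressant": 0.25, "PBS_other": 0.25}

DEFAULT_CPI = {2013: 92.4, 2014: 94.7, 2015: 96.1, 2016: 97.3, 2017: 99.1,
               2018: 100.8, 2019: 100.0}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the defaults are the package's study conditions."""

    n_women: int = 2000
    n_waves: int = 5
    seed: int = 0
    start_year: int = 2013
    # structural coefficients (the recovery targets)
    beta_k10: float = 0.016          # log-cost effect per K10 unit
    gamma_k10: float = 0.02          # positivity logit effect per K10 unit
    alpha_cost: float = 5.7          # log-cost intercept (~$1,000 annual mean)
    sigma_u: float = 0.6             # SD of the individual cost effect
    rho_selection: float = 0.3       # corr(individual cost effect, K10 propensity)
    sigma_eps_by_level: tuple = (0.9, 1.0, 1.1, 1.2)   # none/mild/moderate/severe
    zero_mass_target: float = 0.028  # share of woman-years with zero spending
    year_effect_per_wave: float = 0.02
    covariate_effects_scale: float = 1.0
    confounder_strength: float = 0.0  # planted time-varying omitted confounder
    # K10 process: rounded, clipped latent AR(1) + individual propensity
    k10_mean_wave1: float = 23.0
    k10_trend_per_wave: float = -0.5
    k10_sigma_individual: float = 5.5
    k10_ar_phi: float = 0.5
    k10_ar_sigma: float = 4.0
    # claims expansion
    category_share_params: dict = field(default_factory=lambda: DEFAULT_CATEGORY_SHARES)
    oop_fraction: dict = field(default_factory=lambda: DEFAULT_OOP_FRACTION)
    # claim timing: 0 = uniform over the 12 calendar months; > 0 concentrates
    # distressed women's claims in the months just after their survey month
    # (geometric-style decay at this rate per month of delay)
    monthly_frontload: float = 0.0
    # attrition and deflation
    attrition_rate_per_wave: float = 0.05
    attrition_mechanism: str = "mcar"      # mcar | distress
    cpi_by_year: dict = field(default_factory=lambda: DEFAULT_CPI)

    def __post_init__(self) -> None:
        checks = {
            "n_women": self.n_women >= 2,
            "n_waves": self.n_waves >= 2,
            "sigma_u": self.sigma_u >= 0,
            "rho_selection": abs(self.rho_selection) <= 1,
            "sigma_eps_by_level": (len(self.sigma_eps_by_level) == 4
                                   and all(s >= 0 for s in self.sigma_eps_by_level)),
            "zero_mass_target": 0 <= self.zero_mass_target < 1,
            "attrition_rate_per_wave": 0 <= self.attrition_rate_per_wave < 1,
            "cpi_by_year": all(v > 0 for v in self.cpi_by_year.values()),
            "k10_sigma_individual": self.k10_sigma_individual >= 0,
            "k10_ar_sigma": self.k10_ar_sigma >= 0,
            "attrition_mechanism": self.attrition_mechanism in ("mcar", "distress"),
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid SimConfig field(s): {bad}")


@dataclass
class GroundTruth:
    """Everything needed to recompute the DGP's own answers.

    ``cost_base`` is the per-row log-cost linear index *excluding* the
    beta_k10*K10 term; ``pos_base`` the analogous positivity logit index.
    ``true_effects(...)`` contrasts exact DGP expectations over these rows.
    """

    config: SimConfig
    u: np.ndarray = field(repr=False, default=None)
    k10_propensity: np.ndarray = field(repr=False, default=None)
    kappa0: float = 0.0
    cost_base: np.ndarray = field(repr=False, default=None)
    pos_base: np.ndarray = field(repr=False, default=None)
    k10: np.ndarray = field(repr=False, default=None)
    level_rep_scores: dict = field(default_factory=lambda: {
        "none": 15, "mild": 22, "moderate": 27, "severe": 35})

    def _sigma_for(self, score: int) -> float:
        level = str(k10_levels([score])[0])
        order = {"none": 0, "mild": 1, "moderate": 2, "severe": 3}
        return self.config.sigma_eps_by_level[order[level]]

    def expected_cost(self, score: int) -> np.ndarray:
        """Exact E[cost | K10 set to ``score``] per realized row."""
        c = self.config
        p = expit(self.pos_base + c.gamma_k10 * score)
        mean_pos = np.exp(self.cost_base + c.beta_k10 * score
                          + self._sigma_for(score) ** 2 / 2.0)
        return p * mean_pos

    def expected_positive_cost(self, score: int) -> np.ndarray:
        c = self.config
        return np.exp(self.cost_base + c.beta_k10 * score
                      + self._sigma_for(score) ** 2 / 2.0)

    def true_effects(self, a: int, b: int) -> dict:
        """Conditional and unconditional dollar contrasts of K10 a -> b."""
        return {
            "conditional": float(np.mean(self.expected_positive_cost(b)
                                         - self.expected_positive_cost(a))),
            "unconditional": float(np.mean(self.expected_cost(b)
                                           - self.expected_cost(a))),
        }

    def true_level_effects(self) -> pd.DataFrame:
        """Per-level contrasts vs the 'none' representative score."""
        ref = self.level_rep_scores["none"]
        rows = {}
        for level in ("mild", "moderate", "severe"):
            rows[level] = self.true_effects(ref, self.level_rep_scores[level])
        return pd.DataFrame(rows).T


@dataclass
class SimResult:
    panel: pd.DataFrame
    costs: pd.DataFrame
    truth: GroundTruth
    claims: Optional[pd.DataFrame] = None


def _simulate_k10(cfg: SimConfig, rng: np.random.Generator) -> tuple:
    n, W = cfg.n_women, cfg.n_waves
    z_u = rng.standard_normal(n)
    u = cfg.sigma_u * z_u
    z_ind = (cfg.rho_selection * z_u
             + np.sqrt(max(1 - cfg.rho_selection ** 2, 0.0)) * rng.standard_normal(n))
    a = cfg.k10_sigma_individual * z_ind
    phi, s = cfg.k10_ar_phi, cfg.k10_ar_sigma
    e = np.empty((n, W))
    stat_sd = s / np.sqrt(max(1 - phi ** 2, 1e-12)) if s > 0 else 0.0
    e[:, 0] = stat_sd * rng.standard_normal(n)
    for w in range(1, W):
        e[:, w] = phi * e[:, w - 1] + s * rng.standard_normal(n)
    mu = cfg.k10_mean_wave1 + cfg.k10_trend_per_wave * np.arange(W)
    latent = mu[None, :] + a[:, None] + e
    k10 = np.clip(np.rint(latent), 10, 50).astype(int)
    return k10, u, a


def _simulate_covariates(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n, W = cfg.n_women, cfg.n_waves
    age1 = rng.integers(18, 24, size=n)
    marital1 = rng.choice(MARITAL, size=n, p=[0.70, 0.10, 0.17, 0.03])
    edu1 = rng.integers(0, len(EDUCATION), size=n)
    residence = rng.choice(RESIDENCE, size=n, p=[0.75, 0.18, 0.07])
    state = rng.choice(STATES, size=n,
                       p=[0.32, 0.26, 0.20, 0.07, 0.10, 0.02, 0.01, 0.02])
    rows = []
    marital = marital1.copy()
    edu = edu1.copy()
    card = rng.random(n) < 0.30
    for w in range(W):
        if w > 0:
            switch = rng.random(n) < 0.05
            marital = np.where(switch, rng.choice(MARITAL, size=n), marital)
            upgrade = (rng.random(n) < 0.10) & (edu < len(EDUCATION) - 1)
            edu = edu + upgrade.astype(int)
            card = np.where(rng.random(n) < 0.05, ~card, card)
        rows.append(pd.DataFrame({
            "woman": np.arange(n),
            "wave": w + 1,
            "age": age1 + w,
            "marital": marital,
            "education": np.asarray(EDUCATION, dtype=object)[edu],
            "unemployed": (rng.random(n) < 0.12).astype(int),
            "income_mgmt": (rng.random(n) < 0.25).astype(int),
            "healthcare_card": card.astype(int),
            "residence": residence,
            "state": state,
            "survey_month": rng.integers(1, 13, size=n),
        }))
    return pd.concat(rows, ignore_index=True)


def apply_attrition(panel: pd.DataFrame, attrition_rate_per_wave: float, seed: int,
                    mechanism: str = "mcar",
                    cutoffs=DEFAULT_CUTOFFS) -> pd.DataFrame:
    """Monotone dropout: a per-wave hazard after wave 1; dropped women never return.

    ``mechanism='distress'`` raises the hazard by 60% after a distressed wave.
    """
    if not (0 <= attrition_rate_per_wave < 1):
        raise ValueError(f"attrition rate must be in [0, 1), got {attrition_rate_per_wave}")
    if attrition_rate_per_wave == 0:
        return panel.copy()
    rng = np.random.default_rng(seed)
    waves = sorted(panel["wave"].unique())
    wide = panel.pivot(index="id", columns="wave", values="k10")
    ids = wide.index.to_numpy()
    alive = np.ones(len(ids), dtype=bool)
    last_wave = np.full(len(ids), waves[-1])
    for j, w in enumerate(waves[1:], start=1):
        prev = wide[waves[j - 1]].to_numpy()
        hazard = np.full(len(ids), attrition_rate_per_wave)
        if mechanism == "distress":
            hazard = np.clip(hazard * (1 + 0.6 * (prev > cutoffs.dummy_threshold)), 0, 0.99)
        drop = alive & (rng.random(len(ids)) < hazard)
        last_wave[drop] = waves[j - 1]
        alive &= ~drop
    keep_until = pd.Series(last_wave, index=ids)
    mask = panel["wave"] <= keep_until.reindex(panel["id"]).to_numpy()
    return panel[mask].copy()


def _calibrate_intercept(index: np.ndarray, target_positive: float) -> float:
    """Intercept kappa0 such that mean(sigmoid(kappa0 + index)) = target."""
    if target_positive >= 1.0:
        return 50.0

    def f(k):
        return float(np.mean(expit(k + index))) - target_positive

    return brentq(f, -60, 60, xtol=1e-10)


def simulate_panel(config: SimConfig, with_claims: bool = True) -> SimResult:
    """Generate the panel, annual costs, optional claim lines and GroundTruth.

    Bit-for-bit reproducible from (config, seed).  ``with_claims=False``
    skips the claim-line expansion (the annual cost table is exact either
    way) for simulation studies that refit the model many times.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    k10_wide, u, a = _simulate_k10(cfg, rng)
    cov = _simulate_covariates(cfg, rng)
    n, W = cfg.n_women, cfg.n_waves

    panel = cov.copy()
    panel["k10"] = k10_wide[panel["woman"].to_numpy(), panel["wave"].to_numpy() - 1]
    panel["year"] = cfg.start_year + panel["wave"] - 1
    panel["id"] = panel["woman"] + 1
    panel = panel.drop(columns="woman")

    # attrition on the full balanced panel, then costs for the observed rows
    panel = apply_attrition(panel, cfg.attrition_rate_per_wave,
                            seed=cfg.seed + 1, mechanism=cfg.attrition_mechanism)
    panel = panel.reset_index(drop=True)

    scale = cfg.covariate_effects_scale
    eta_x = scale * sum(_ETA[c] * panel[c].to_numpy(dtype=float) for c in _ETA)
    year_eff = cfg.year_effect_per_wave * (panel["wave"].to_numpy() - 1)
    u_row = u[panel["id"].to_numpy() - 1]
    conf = np.zeros(len(panel))
    if cfg.confounder_strength != 0:
        # time-varying confounder: correlated with the K10 innovation and the cost
        z = rng.standard_normal(len(panel))
        conf = cfg.confounder_strength * (0.05 * (panel["k10"].to_numpy()
                                                  - panel["k10"].mean()) + z)
    cost_base = cfg.alpha_cost + eta_x + year_eff + u_row + conf
    pos_cov = scale * sum(_GAMMA_X[c] * panel[c].to_numpy(dtype=float) for c in _GAMMA_X)
    k10_row = panel["k10"].to_numpy()
    index_nokappa = cfg.gamma_k10 * k10_row + pos_cov
    kappa0 = _calibrate_intercept(index_nokappa, 1.0 - cfg.zero_mass_target)

    levels = k10_levels(k10_row)
    order = {"none": 0, "mild": 1, "moderate": 2, "severe": 3}
    sig = np.asarray(cfg.sigma_eps_by_level)[[order[str(l)] for l in levels]]
    eps = sig * rng.standard_normal(len(panel))
    log_cost = cost_base + cfg.beta_k10 * k10_row + eps
    p_pos = expit(kappa0 + index_nokappa)
    positive = rng.random(len(panel)) < p_pos
    total = np.where(positive, np.exp(log_cost), 0.0)

    costs = pd.DataFrame({"id": panel["id"], "wave": panel["wave"],
                          "year": panel["year"], "total": total,
                          "positive_total": positive})
    truth = GroundTruth(config=cfg, u=u, k10_propensity=a, kappa0=kappa0,
                        cost_base=cost_base, pos_base=kappa0 + pos_cov,
                        k10=k10_row)

    claims = _expand_claims(cfg, panel, costs, rng) if with_claims else None
    return SimResult(panel=panel[["id", "wave", "year", "k10", "age", "marital",
                                  "education", "unemployed", "income_mgmt",
                                  "healthcare_card", "residence", "state",
                                  "survey_month"]],
                     costs=costs, truth=truth, claims=claims)


def _expand_claims(cfg: SimConfig, panel: pd.DataFrame, costs: pd.DataFrame,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Split each positive annual total into dated claim lines by category.

    Category shares are Dirichlet draws whose mental-health concentration
    rises with K10; each category amount is split over 1-3 claims placed
    uniformly over the 12 calendar months.  Amounts are written in nominal
    (year-of-service) dollars so that CPI deflation recovers the 2019 totals.
    """
    share = cfg.category_share_params
    cats = list(share["base"].keys())
    base_w = np.array([share["base"][c] for c in cats])
    slope = np.array([share["slope"].get(c, 0.0) for c in cats])
    conc = float(share.get("concentration", 4.0))

    pos = costs["positive_total"].to_numpy()
    rows = np.flatnonzero(pos)
    if len(rows) == 0:
        return pd.DataFrame(columns=["id", "date", "scheme", "category",
                                     "benefit", "oop"])
    k10 = panel["k10"].to_numpy()[rows]
    tilt = np.exp(slope[None, :] * (k10[:, None] - 10) / 40.0)
    w = base_w[None, :] * tilt
    alpha = conc * w / w.sum(axis=1, keepdims=True)
    g = rng.gamma(shape=alpha)
    shares = g / g.sum(axis=1, keepdims=True)
    amounts = shares * costs["total"].to_numpy()[rows][:, None]   # 2019 dollars

    r_idx, c_idx = np.nonzero(amounts > 0.005)
    amt = amounts[r_idx, c_idx]
    n_claims = 1 + rng.poisson(0.7, size=len(amt))
    seg = np.repeat(np.arange(len(amt)), n_claims)
    gpart = rng.exponential(1.0, size=len(seg)) + 0.05
    part_share = gpart / np.bincount(seg, weights=gpart)[seg]
    claim_amt = amt[seg] * part_share

    row_of_claim = rows[r_idx][seg]
    cat_of_claim = np.asarray(cats, dtype=object)[c_idx][seg]
    year = costs["year"].to_numpy()[row_of_claim]
    if cfg.monthly_frontload > 0:
        # distressed rows: month offset from the survey month with decaying
        # probability (wrapped within the calendar year); others uniform
        offs = np.arange(12)
        p_off = np.exp(-cfg.monthly_frontload * offs)
        p_off = p_off / p_off.sum()
        offset = rng.choice(12, size=len(seg), p=p_off)
        survey = panel["survey_month"].to_numpy()[row_of_claim]
        distressed = panel["k10"].to_numpy()[row_of_claim] > 24
        month_fl = ((survey - 1 + offset) % 12) + 1
        month_unif = rng.integers(1, 13, size=len(seg))
        month = np.where(distressed, month_fl, month_unif)
    else:
        month = rng.integers(1, 13, size=len(seg))
    day = rng.integers(1, 29, size=len(seg))
    cpi = cfg.cpi_by_year
    base_idx = cpi[2019]
    nominal = claim_amt * np.array([cpi[int(y)] / base_idx for y in year])
    oop_rate = np.array([cfg.oop_fraction.get(c, 0.2) for c in cat_of_claim])
    scheme = np.where(pd.Series(cat_of_claim).str.startswith("PBS").to_numpy(),
                      "PBS", "MBS")
    dates = pd.to_datetime({"year": year, "month": month, "day": day})
    return pd.DataFrame({
        "id": costs["id"].to_numpy()[row_of_claim],
        "date": dates,
        "scheme": scheme,
        "category": cat_of_claim,
        "benefit": nominal,
        "oop": nominal * oop_rate,
    }).sort_values(["id", "date"], kind="stable").reset_index(drop=True)
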