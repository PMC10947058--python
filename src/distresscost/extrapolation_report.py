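"""Population extrapolation of per-woman excess costs, and the end-to-end
pipeline that sequences simulation/IO, descriptives, the two-part fits,
bootstrapped effects, selection diagnostics, chronicity and monthly-window
analyses, and the final extrapolation report."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import claims_io, descriptives, distress_coding, oster_bounds
from .claims_io import DeflatorTable
from .panel_estimators import DesignSpec, build_design, fit
from .synthetic_cohort import SimConfig, simulate_panel
from .two_part_effects import cluster_bootstrap, fit_two_part, incremental_effect

# Reference values for the worked-example report: Australian women aged 18-27
# by distress level, and 2019-20 government spending on Medicare-subsidised
# mental-health services and PBS/RPBS mental-health prescriptions (AUD millions).
DEFAULT_POPULATIONS = {
    "counts": {"mild": 361_925, "moderate": 241_283, "severe": 310_222},
    "total": 1_720_000,
    "reference_spending_millions": 1966.0,
    "reference_label": "Medicare-subsidised mental health services + PBS/RPBS "
                       "mental-health prescriptions, 2019-20",
}


@dataclass(frozen=True)
class PopulationTable:
    """Population counts per distress level and a reference spending total."""

    counts: dict
    total: int = None
    reference_spending_millions: float = None
    reference_label: str = ""

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("population counts must be non-negative")
        if self.total is not None and sum(self.counts.values()) > self.total:
            raise ValueError("level counts exceed the total reference population")


def extrapolate(per_woman_effects: dict, populations: PopulationTable,
                levels=None) -> pd.DataFrame:
    """Level totals in AUD millions: per-woman effect x population / 1e6.

    Adds a ``combined`` row summing the requested levels.
    """
    levels = list(per_woman_effects.keys()) if levels is None else list(levels)
    rows = {}
    for lv in levels:
        if lv not in per_woman_effects:
            raise ValueError(f"no per-woman effect for level {lv!r}")
        if lv not in populations.counts:
            raise ValueError(f"no population count for level {lv!r}")
        rows[lv] = {
            "per_woman_effect": float(per_woman_effects[lv]),
            "population": int(populations.counts[lv]),
            "total_millions": float(per_woman_effects[lv])
            * populations.counts[lv] / 1e6,
        }
    out = pd.DataFrame(rows).T
    combined = out["total_millions"].sum()
    out.loc["combined"] = {"per_woman_effect": np.nan, "population":
                           int(out["population"].sum()), "total_millions": combined}
    return out


def share_of_reference(total_millions: float, reference_millions: float) -> float:
    """Extrapolated total as a percentage of the reference spending."""
    if reference_millions <= 0:
        raise ValueError("reference spending must be positive")
    return 100.0 * total_millions / reference_millions


# ---------------------------------------------------------------------------
# pipeline


DEFAULT_CONFIG = {
    "simulate": {"n_women": 200, "n_waves": 5, "seed": 0},
    "deflators": {"base_year": 2019, "index": None},   # None -> generator CPI
    "cutoffs": {},
    "analysis": {"outcome": "total", "estimators": ["FE", "RE", "OLS"]},
    "bootstrap": {"B": 50, "seed": 0},
    "oster": {"rmax_multipliers": [1.3, 2.2], "delta": 1.0},
    "populations": DEFAULT_POPULATIONS,
    "monthly": {"windows": list(range(1, 13))},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config, out_dir, seed: int = None) -> dict:
    """Run every stage and write tables + a machine-readable summary.

    ``config`` is a YAML path or dict; ``seed`` overrides the config seeds.
    Any stage failure raises :class:`PipelineError` naming the stage; tables
    already written are left in place.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        cfg["simulate"]["seed"] = int(seed)
        cfg["bootstrap"]["seed"] = int(seed)
    summary = {"config_seed": cfg["simulate"].get("seed"),
               "bootstrap_seed": cfg["bootstrap"].get("seed")}
    stage = "setup"
    try:
        stage = "simulate"
        sim_kwargs = {k: v for k, v in cfg["simulate"].items()}
        sim_cfg = SimConfig(**sim_kwargs)
        sim = simulate_panel(sim_cfg, with_claims=True)
        panel, claims = sim.panel, sim.claims
        claims_io.write_panel(panel, out / "panel.csv")
        claims_io.write_claims(claims, out / "claims.csv")

        stage = "aggregate"
        defl_cfg = cfg["deflators"]
        index = defl_cfg.get("index") or sim_cfg.cpi_by_year
        deflators = DeflatorTable(index={int(k): float(v) for k, v in index.items()},
                                  base_year=int(defl_cfg.get("base_year", 2019)))
        agg = claims_io.aggregate_annual(claims, panel, deflators)
        costs = agg.costs
        costs.to_csv(out / "annual_costs.csv", index=False)
        summary["n_woman_waves"] = int(len(costs))
        summary["pct_positive"] = round(100 * float(costs["positive_total"].mean()), 2)

        stage = "describe"
        summ = descriptives.cost_summary_by_level(costs, panel)
        summ.to_csv(out / "table_costs_by_level.csv")
        descriptives.level_contrasts(summ).to_csv(out / "table_level_contrasts.csv")
        merged = panel.merge(costs, on=["id", "wave"])
        curve = descriptives.local_mean_smoother(merged["k10"], merged["total"])
        curve.to_csv(out / "curve_cost_by_k10.csv", index=False)

        stage = "fit"
        outcome = cfg["analysis"]["outcome"]
        coef_rows = []
        fits = {}
        for est in cfg["analysis"]["estimators"]:
            for expo in ("k10", "distress_dummy", "level_dummies"):
                spec = DesignSpec(outcome=outcome, exposure=expo, estimator=est)
                tpf = fit_two_part(panel, costs, spec)
                fits[(est, expo)] = tpf
                for part, f in (("positive", tpf.part1), ("log", tpf.part2)):
                    t = f.tidy()
                    for c in tpf.design1.exposure_cols:
                        if c in t.index:
                            coef_rows.append({"estimator": est, "exposure": expo,
                                              "part": part, "term": c,
                                              **t.loc[c].to_dict(),
                                              "n": f.n, "r2": f.r2})
        pd.DataFrame(coef_rows).to_csv(out / "table_coefficients.csv", index=False)

        stage = "effects"
        B = int(cfg["bootstrap"]["B"])
        bseed = int(cfg["bootstrap"]["seed"])
        eff_rows = []
        contrasts = {"k10": (22, 23), "distress_dummy": (0, 1),
                     "level_dummies": [("none", "mild"), ("none", "moderate"),
                                       ("none", "severe")]}
        for (est, expo), tpf in fits.items():
            cons = contrasts[expo]
            cons = cons if isinstance(cons, list) else [cons]
            for con in cons:
                if B >= 2:
                    eff = cluster_bootstrap(tpf, con, B=B, seed=bseed)
                else:
                    warnings.warn("bootstrap.B < 2; effects reported without SEs")
                    eff = incremental_effect(tpf, con)
                eff_rows.append({
                    "estimator": est, "exposure": expo,
                    "contrast": f"{con[0]}->{con[1]}",
                    "conditional": round(eff.conditional, 2),
                    "conditional_se": round(eff.conditional_se, 2)
                    if np.isfinite(eff.conditional_se) else None,
                    "unconditional": round(eff.unconditional, 2),
                    "unconditional_se": round(eff.unconditional_se, 2)
                    if np.isfinite(eff.unconditional_se) else None,
                    "B": eff.B,
                })
        eff_df = pd.DataFrame(eff_rows)
        eff_df.to_csv(out / "table_effects.csv", index=False)

        stage = "oster"
        oster_rows = []
        for expo in ("k10", "distress_dummy"):
            spec = DesignSpec(outcome=f"log_{outcome}", exposure=expo, estimator="FE")
            inputs = oster_bounds.fit_baseline_controlled(panel, costs, spec)
            tab = oster_bounds.oster_table(
                inputs, multipliers=tuple(cfg["oster"]["rmax_multipliers"]),
                delta=float(cfg["oster"]["delta"]))
            tab.insert(0, "exposure", expo)
            oster_rows.append(tab)
        pd.concat(oster_rows).round(3).to_csv(out / "table_oster.csv", index=False)

        stage = "chronicity"
        chron = _chronicity_stage(panel, costs, outcome)
        chron.to_csv(out / "table_chronicity.csv", index=False)

        stage = "monthly"
        monthly = _monthly_stage(panel, claims, deflators, cfg["monthly"]["windows"])
        monthly.to_csv(out / "table_monthly.csv", index=False)

        stage = "extrapolate"
        pops = PopulationTable(**{k: v for k, v in cfg["populations"].items()
                                  if k in ("counts", "total",
                                           "reference_spending_millions",
                                           "reference_label")})
        fe_levels = eff_df[(eff_df["estimator"] == "FE")
                           & (eff_df["exposure"] == "level_dummies")]
        per_woman = {row["contrast"].split("->")[1]: row["unconditional"]
                     for _, row in fe_levels.iterrows()}
        extr = extrapolate(per_woman, pops, levels=["mild", "moderate", "severe"])
        extr.round(2).to_csv(out / "table_extrapolation.csv")
        mod_sev = float(extr.loc[["moderate", "severe"], "total_millions"].sum())
        summary["extrapolated_combined_moderate_severe_millions"] = round(mod_sev, 2)
        if pops.reference_spending_millions:
            summary["share_of_reference_pct"] = round(
                share_of_reference(mod_sev, pops.reference_spending_millions), 2)
        summary["fe_k10_log_coef"] = round(
            float(fits[("FE", "k10")].part2.params["k10"]), 6)
        summary["fe_dummy_unconditional"] = float(
            eff_df[(eff_df["estimator"] == "FE")
                   & (eff_df["exposure"] == "distress_dummy")]["unconditional"].iloc[0])
    except Exception as exc:           # noqa: BLE001 - stage name is the contract
        raise PipelineError(stage, exc) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _chronicity_stage(panel: pd.DataFrame, costs: pd.DataFrame,
                      outcome: str) -> pd.DataFrame:
    """Onset/chronicity fits on the balanced onset sample.

    For each persistence threshold k, the exposure is the woman-wave distress
    dummy restricted to women distressed in at least k post-baseline waves.
    """
    waves = sorted(panel["wave"].unique())
    bal = distress_coding.balance_panel(panel, waves)
    if bal.empty:
        return pd.DataFrame()
    sample, flags = distress_coding.build_onset_sample(bal)
    rows = []
    thresholds = [("onset_any", 1), ("at_least_2", 2), ("at_least_3", 3),
                  ("all_4", len(waves) - 1)]
    dummy = distress_coding.distress_dummy(sample["k10"].to_numpy())
    for name, _k in thresholds:
        chronic_women = flags.table.index[flags.table[name]
                                          & flags.table["kept_in_sample"]]
        expo_col = dummy * sample["id"].isin(chronic_women).to_numpy()
        s = sample.assign(chronic=expo_col.astype(float))
        if s["chronic"].std() == 0:
            continue
        spec = DesignSpec(outcome=outcome, exposure="chronic", estimator="FE")
        try:
            tpf = fit_two_part(s, costs, spec)
        except ValueError:
            continue
        rows.append({"definition": name,
                     "positive_coef": float(tpf.part1.params.get("chronic", np.nan)),
                     "log_coef": float(tpf.part2.params.get("chronic", np.nan)),
                     "log_se": float(tpf.part2.se.get("chronic", np.nan)),
                     "n": tpf.part2.n,
                     "pct_with_distress": round(100 * float(s.groupby("id")["chronic"]
                                                            .max().mean()), 1)})
    return pd.DataFrame(rows)


def _monthly_stage(panel: pd.DataFrame, claims: pd.DataFrame,
                   deflators: DeflatorTable, windows) -> pd.DataFrame:
    """Part-2 K10 coefficient on log T_k cost for each window length k."""
    rows = []
    for k in windows:
        win = claims_io.aggregate_window(claims, panel, int(k), deflators)
        win["positive_window_cost"] = win["window_cost"] > 0
        spec = DesignSpec(outcome="window_cost", exposure="k10", estimator="FE")
        try:
            tpf = fit_two_part(panel, win, spec)
        except ValueError:
            continue
        rows.append({"window_months": int(k),
                     "log_coef_k10": float(tpf.part2.params.get("k10", np.nan)),
                     "se": float(tpf.part2.se.get("k10", np.nan)),
                     "n_positive": tpf.part2.n})
    return pd.DataFrame(rows)
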