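# distresscost

Estimating the excess healthcare costs attributable to psychological distress
in young women, from linked survey + administrative claims panels.

## The problem

Psychological distress (measured by the Kessler-10 scale, an integer score in
10–50 from ten items each scored 1–5) is common in young adults and is
associated with higher use of subsidised health services — GP, specialist and
allied-health attendances under Australia's Medicare Benefits Schedule (MBS)
and prescriptions under the Pharmaceutical Benefits Scheme (PBS). Simply
comparing spending across distress levels conflates distress with stable
individual traits (reporting style, genetic predisposition, health literacy)
that drive both distress and healthcare use. This package implements the
standard health-economics answer: a **two-part panel cost model with
individual fixed effects**, plus the surrounding machinery needed to turn
claim lines into estimands and dollar figures.

## The model

For woman *i* in year *t*, with K10 score `K10_it` and covariates `X_it`:

1. extensive margin (linear probability model):
   `1{cost_it > 0} = α₁ + β₁ K10_it + η₁′X_it + φ₁ᵢ + γ₁ₜ + ε₁it`
2. intensive margin, conditional on any spending:
   `log cost_it = α₂ + β₂ K10_it + η₂′X_it + φ₂ᵢ + γ₂ₜ + ε₂it`

Both parts are estimated by the within (fixed-effects) estimator — with
random-effects (Swamy–Arora) and pooled OLS for comparison — and standard
errors clustered on the woman. Log-scale predictions are retransformed to
dollars with the Duan smearing factor `E[exp(ε̂)]`, computed separately by
distress level to respect heteroskedasticity. Incremental dollar effects
contrast counterfactual exposure states (K10 s→s+1, distress dummy 0→1,
level none→severe), with cluster-bootstrap standard errors that re-run the
whole pipeline per replicate. Sensitivity to selection on unobservables is
assessed with proportional-selection (coefficient-stability) bounds:
`β* = β̃ − δ(β̇ − β̃)(R_max − R̃)/(R̃ − Ṙ)`. Per-woman effects are
extrapolated to population totals by distress level.

Because the real linked survey/claims data are access-restricted, the package
ships a first-class synthetic generator (`synthetic_cohort`) that emulates the
panel's statistical structure — ~97% positive annual spending, right-skewed
costs rising with distress, mental-health category shares steepening with
K10, monotone attrition — with a recorded `GroundTruth` so parameter-recovery
and calibration claims are testable.

## Worked example

```python
import distresscost as dc

cfg = dc.SimConfig(n_women=2000, seed=42)        # ~9,000 woman-years, 5 waves
sim = dc.simulate_panel(cfg, with_claims=False)

spec = dc.DesignSpec(outcome="total", exposure="distress_dummy", estimator="FE")
tpf = dc.fit_two_part(sim.panel, sim.costs, spec)
print(tpf.part2.params["distress_dummy"], tpf.part2.se["distress_dummy"])
# 0.1646 0.0439   -> distressed women (K10 > 24) spend ~16% more | any spending

eff = dc.cluster_bootstrap(tpf, (0, 1), B=200, seed=42)
print(eff.unconditional, eff.unconditional_se)
# 394.86 59.17    -> ~$395/year extra in 2019 AUD (bootstrap SE across women)
```

The extensive-margin coefficient (0.0132, SE 0.0061) is small — almost
everyone has some spending — so the dollar effect is driven by the intensive
margin, as expected when ~97% of woman-years have positive costs.

From the shell, the same pipeline end to end:

```bash
distresscost run-all --out out --seed 7
distresscost extrapolate --mild 93.14 --moderate 179.03 --severe 309.60
#           per_woman_effect  population  total_millions
# mild                 93.14    361925.0           33.71
# moderate            179.03    241283.0           43.20
# severe              309.60    310222.0           96.04
# moderate+severe = 139.24M = 7.1% of reference
```

i.e. given published per-woman effects and level populations, moderate plus
severe distress accounts for roughly $139M a year, about 7% of the reference
government mental-health spending total.

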