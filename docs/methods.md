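# Methods

## Estimands and model

The quantity of interest is the excess annual healthcare cost attributable to
psychological distress: the difference in expected annual subsidised spending
(non-hospital MBS plus PBS, 2019 AUD) between counterfactual distress states,
per woman-year. Costs are semicontinuous — a small zero mass and a
right-skewed positive part — so the model is the classical two-part
decomposition: a linear probability model for any spending, and a linear
model for log spending on the positive-cost rows. Both parts are linear panel
models with individual fixed effects (within estimator), year dummies and
observed covariates; random-effects (Swamy–Arora feasible GLS) and pooled OLS
variants are provided for comparison. The individual effect absorbs stable
traits (reporting style, genetic predisposition, preferences) that would
otherwise bias a cross-sectional slope; with a positive correlation between
those traits and distress, the pooled slope overstates the within slope,
which is exactly the pattern the generator plants and the tests check
(FE < RE < OLS).

Standard errors are clustered on the woman with the sandwich estimator and
small-sample scaling `G/(G−1) · (N−1)/(N−K)`; for the within estimator the
`K` in the degrees-of-freedom term includes the `G` absorbed individual
effects. With every observation its own cluster the formula reduces exactly
to HC1, which is tested.

## Retransformation and dollar effects

Predictions on the dollar scale multiply the part-1 probability, clipped to
[0, 1] (clipping incidence is the price of the LPM), by `exp(linear
predictor)` from part 2 times a Duan smearing factor — the mean of
exponentiated part-2 residuals. Costs are more dispersed at higher distress,
so smearing factors are computed separately by distress group: the four K10
levels when the exposure is the score or level dummies, the two exposure
states for binary exposures; per-integer-score grouping is available behind
`smearing_grouping="score"` but the level grouping is the default because
per-score cells get small and noisy. FE predictions include the estimated
individual effect; in a counterfactual contrast only the exposure columns
change, so the individual effect persists on both sides (it does not cancel
after exponentiation). Women absent from the positive-cost subsample (about
3% of rows) have no part-2 individual effect and receive the mean effect.

Conditional effects average the smeared part-2 prediction difference over the
estimation sample; unconditional effects average the full product. The mean
of the unconditional prediction reproduces the sample mean cost only
approximately (LPM clipping and smearing-by-group break exact adding-up); on
the default synthetic fixture the gap is ~0.5% and the test bound is 2%.

Uncertainty comes from a cluster bootstrap: whole women are resampled with
replacement, every copy treated as a distinct cluster, and the entire
pipeline — both fits and the smearing table — is re-run per replicate
(B = 200 by default, percentile intervals). The replicate engine operates on
the design arrays built once from the data; since the design build is
deterministic row-wise this is identical to rebuilding from resampled tables,
and a test asserts the identity resample reproduces the full-pipeline point
estimate exactly.

## Selection on unobservables

Robustness to omitted time-varying confounders uses the proportional-
selection approximation `β* = β̃ − δ(β̇ − β̃)(R_max − R̃)/(R̃ − Ṙ)` and its
inverse `δ*` for β = 0, with `R_max ∈ {1.3, 2.2} × R̃` capped at 1. Baseline
(exposure + year dummies + individual effects) and controlled fits are forced
onto the identical sample, and both use the same R² definition — within R²
for FE fits, overall R² otherwise; which definition feeds the bounds is a
genuine convention choice and is configurable. The full cubic estimator,
which requires auxiliary variance/covariance moments, is a documented
extension point and not implemented.

## Claims aggregation

Claim lines carry a scheme (MBS/PBS), a category, the government benefit and
the patient's out-of-pocket amount. Annual costs assign each claim to the
woman's wave whose calendar year contains the service date; claims dated
outside any panel year are routed to an `unassigned` report rather than
dropped. Hospital MBS lines are excluded by default so totals mean
non-hospital MBS + PBS benefits. Amounts are deflated to 2019 AUD by
`amount × I(2019)/I(year)` from a configurable CPI table; rounding to cents
happens only at report time. Monthly windows T₁…T₁₂ start at each woman's
survey-return month (inclusive) and roll over the year boundary; T_k is
non-decreasing in k and a January survey's T₁₂ equals the annual total.
Out-of-pocket "mental-health related" means the consultant-psychiatry and
mental-health allied categories; the raw-category → reporting-group map is
config-supplied since programs, not item numbers, define the split.

## The synthetic generator

`synthetic_cohort` emulates the study conditions: ~5 annual waves from 2013,
an unbalanced panel with monotone MCAR attrition (hazard 0.05/wave; a
distress-dependent variant is available, default MCAR since the real
mechanism is uncharacterised), K10 as a rounded clipped latent AR(1) (φ=0.5,
innovation SD 4) plus an individual propensity (SD 5.5) with a declining mean
(23 → 21 over five waves), and a 97.2% positive-spending share enforced by
numerically calibrating the positivity-logit intercept to the realized index.
Log positive cost is `α + 0.016·K10 + η′X + uᵢ + year effect + ε` with ε SD
(0.9, 1.0, 1.1, 1.2) by distress level and `uᵢ ~ N(0, 0.6²)` correlated 0.3
with the K10 propensity; α = 5.7 puts mean annual cost near $1,200.
Positive totals split into dated claim lines via Dirichlet category shares
whose mental-health concentration rises with K10, then into 1–3 claims per
category placed uniformly over the 12 calendar months (a `monthly_frontload`
option concentrates distressed women's claims just after the survey month,
to study the timing-mismatch question). Amounts are written nominal so CPI
deflation recovers the 2019 totals; category amounts under half a cent are
not expanded into claims.

Because positivity is logistic while estimation is linear, true effects are
defined by contrasting DGP expectations, not coefficients: `GroundTruth`
stores the per-row cost and positivity indices and evaluates
`E[cost | K10=s] = sigmoid(·) · exp(·) · exp(σ²_level/2)` exactly over the
realized rows (an exact expectation where a Monte-Carlo average would only
add noise; an independent Monte-Carlo check of this closed form is in the
tests). The default scale for simulation studies is 2,000 women × 5 waves —
a desk scale chosen so the full suite of replication studies (100-replicate
parameter recovery, 200×B=200 bootstrap calibration at 500 women) completes
in minutes while leaving the asymptotics recognisable.

What the generator does **not** emulate: the real covariate joint
distribution, item nonresponse, bulk-billing and rebate-schedule detail, or
hospital spending. Passing recovery tests therefore show the estimator
machinery is correct under the stated DGP, not that the published
coefficients would be reproduced on the restricted data.

## Numerical conventions

- Natural logarithms throughout; ISO-8601 dates; calendar months.
- Within/RE/OLS solved by `lstsq`; rank-deficient (collinear) columns get the
  minimum-norm solution, which leaves fitted values and exposure coefficients
  unaffected; zero-variance and time-invariant-under-FE columns are dropped
  with warnings.
- FE R² is the within R²; RE reports overall R². FE degrees of freedom
  subtract the G estimated individual effects.
- Listwise deletion of incomplete rows, with a count, mirrors the sample
  construction of the study design.
- Categorical covariates expand against the first sorted level as reference.
- Bootstrap replicates that fail (empty positive subsample) are counted;
  more than 10% failures aborts.
- A single-cluster fit returns NaN cluster-robust SEs with a warning rather
  than refusing to estimate.

## Known limitations

- The LPM part-1 can predict outside [0, 1]; clipping introduces a small
  adding-up error in unconditional predictions (bounded in tests at 2%).
- Proportional-selection bounds use the linearised approximation, not the
  cubic estimator; the two differ when selection is strong.
- RE effects use `Xβ` without best-linear-unbiased predictions of the
  individual effects.
- Extrapolated totals are point calculations; no uncertainty is propagated
  into the population figures.
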