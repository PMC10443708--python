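# Methods

`fopl_impact` models the dietary and mortality consequences of consumers
responding to mandatory 'high in' front-of-package nutrition symbols by
substituting packaged foods with similar, less-flagged alternatives. The
pipeline has six stages; each is an importable module, and
`report.run_full_pipeline` chains them deterministically under a single
seed.

## Symbol classification (`classify`)

A food displays a 'high in' symbol for sodium, total sugars or saturated
fat when its content in the *evaluation basis* meets or exceeds a
percent-daily-value threshold. The rules implemented are a simplified
reading of the 2022 Canadian front-of-package regulations:

| rule | basis | threshold |
|---|---|---|
| general prepackaged food | reference amount (RA), or the stated serving if larger | 15% DV |
| main dish, RA >= 200 g | RA / serving | 30% DV |
| small RA (<= 30 g) | fixed 50 g | 15% DV |

Daily values default to sodium 2,300 mg, total sugars 100 g, saturated
fat 20 g. Every constant — daily values, fractions, RA cutoffs, exempt
categories — lives in `ThresholdPolicy` and can be overridden; the
package takes no position on regulatory minutiae beyond these three
rules. Comparisons are `>=` ("meet or exceed") with a 1e-9 relative
slack so amounts constructed exactly on a threshold are flagged despite
float rounding. Energy and fiber are never symbol nutrients; exemptions
are category-level flags, not ingredient logic.

## Alternative matching (`matching`)

A branded product is a *healthier alternative* to a consumed generic
food when it shares the food's minor category and displays **strictly
fewer** symbols. The substitution profile of a food is the unweighted
arithmetic per-100 g mean of its alternatives (median by option);
"aggregated nutrient values" admits several readings and the mean is the
simplest defensible one. When alternatives reduce *different* symbols,
the aggregate may not itself display fewer symbols; the aggregate is
re-classified, its count recorded, and a warning emitted — no filtering,
since the selection criterion is defined on the individual products.

## Substitution scenarios (`scenario`)

Eligibility: any respondent who consumed at least one 'high in' food on
either recall day, whether or not an alternative exists for it (a strict
mode that requires substitutability is a flag; it changes the effective
dose). A simple random sample of `round(fraction x eligible)`
respondents (half-away-from-zero rounding, for platform-stable sizes) is
drawn per scenario at fractions 0.30/0.50/0.70/1.00, reflecting the
range of observed consumer response to nutrient-warning labels.
Scenario draws are independent across scenarios (not nested), each with
its own derived seed. For selected respondents, every recall item whose
food has an alternative set gets the aggregate per-100 g values of
energy, sodium, sugars, saturated fat and fiber; gram amounts never
change, so substitution is idempotent and weight-preserving. Saturated
fat %TE is derived as `satfat_g x 9 / energy_kcal x 100` (Atwater
factor), NaN for zero-energy days.

## Usual-intake estimation (`usual_intake`)

Two 24-h recalls per person mix usual intake with day-to-day noise. The
estimator is a one-part (amount-only) measurement-error model in the
NCI-method family, reduced to what the downstream contract needs
(means ± SEs; percentiles and inadequacy prevalence are out of scope):

1. **Misreporting status.** TEE is predicted per respondent
   (Mifflin-St Jeor resting expenditure x activity level 1.6;
   replaceable), and Goldberg-style cutoffs on the 2-day-mean EI:TEE
   ratio (defaults 0.7 / 1.42) classify under/plausible/over-reporters.
2. **Transform and fit.** Daily totals are Box-Cox transformed; lambda
   is chosen on a 0.05–1.00 grid (step 0.05) maximizing the Gaussian
   random-intercept likelihood plus the Box-Cox Jacobian. With a
   balanced 2-day design the mixed likelihood has a closed form
   (person-mean and person-difference components), and person/day
   variance components are survey-weighted method-of-moments estimates:
   `var_within = E[(r1 - r2)^2]/2`, `var_between = var(person means) -
   var_within x mean(1/n_days)`, clipped at zero. Covariates: sex, DRI
   age group, weekend, recall sequence, misreporting status. Outliers
   with |standardized transformed residual| > 4 are removed once and the
   model refitted at the chosen lambda.
3. **Back-transform.** A person's usual intake is
   `g_inv(m) + 0.5 g_inv''(m) var_within`, where `m` is the shrunken
   (BLUP-style) person mean predicted at reference day-level covariates
   (weekend at its 2/7 frequency, first recall, *plausible* reporting —
   the last removes the planted reporting bias). Stratum means are
   survey-weighted averages; strata are overall plus the eight DRI
   age-sex groups; strata under 10 respondents are flagged unstable.
4. **Uncertainty.** Ordinary respondent bootstrap, 500 replicates,
   percentile 95% CIs. Replicates refit coefficients and variance
   components at the point-estimate lambda — the transform is a nuisance
   parameter and re-running the grid inside the bootstrap buys nothing
   at 40x the cost. The replicate-weight (balanced repeated replication)
   design of the original survey is not reconstructible from public
   structure, so the SE contract is met with the ordinary bootstrap.
   Scenario differences are "meaningful" only when the two 95% intervals
   are disjoint; a shared endpoint counts as overlap. No p-values.

**Known limitation.** The second-order back-transform assumes
transformed-scale residuals are approximately normal. In the synthetic
world, day-level noise for strongly skewed nutrients (sodium, fiber) is
a mixture (menu composition), and the estimator sits ~4–6% below the
generated truth for those nutrients; energy, whose noise is log-normal
by construction, is calibrated (CI coverage ~95%). Baseline and
counterfactual share the bias, so scenario deltas are unaffected. Real
recall data have the same issue in milder form; this is a property of
the method, not a defect of the implementation.

## Risk assessment (`prime`)

A cross-sectional comparative risk assessment in the Preventable Risk
Integrated ModEl tradition: how many deaths in the baseline year would
not have occurred under the counterfactual risk-factor distribution?

* **Mediation.** Energy change -> steady-state weight at `k = 22`
  kcal/day per kg -> BMI via stratum mean height; sodium -> salt
  (2.5 g per 1,000 mg) -> systolic blood pressure via age-banded
  coefficients (0.55 / 1.0 / 1.45 mmHg per g salt below 40 / 40–59 /
  60+, an age-rising simplification of the published salt–pressure
  dose-response); saturated fat %TE -> serum cholesterol at 0.05
  mmol/L per percentage point; fiber acts directly. Total sugars have
  no pathway of their own — their effect rides on the energy change.
  Counterfactual distributions shift the mean only, SD unchanged (the
  simplest reading of "a different distribution" given mean-only
  pipeline inputs).
* **Expected relative risk.** Log-linear dose-response
  `RR(x) = rr^((x - x_ref)/unit)`. For normal exposures
  `E[RR] = exp(beta mu' + beta^2 sigma^2/2)` exactly; the public
  `expected_rr` uses adaptive quadrature and agrees with the closed form
  to 1e-6 relative (a property-tested invariant). Log-normal exposures
  have no finite `E[exp(beta X)]` for harmful RRs, so non-normal shapes
  are truncated at quantile 1e-8 per tail and renormalized; the fast
  Monte Carlo path evaluates the same truncated integral with 96-node
  Gauss-Legendre quadrature.
* **Impact.** `PIF = 1 - E[RR_cf]/E[RR_base]` per stratum (sex x
  five-year age band), cause and factor; factors combine as
  `1 - prod(1 - PIF_f)`; deaths averted = PIF x baseline deaths. BMI is
  log-normal by default, blood pressure, cholesterol and fiber normal.
* **Uncertainty.** The central estimate uses point RRs (the model's
  convention, and stable to report). Each of 10,000 Monte Carlo
  iterations redraws `ln RR ~ N(ln rr, ln_rr_se)` independently per
  (factor, cause) and recomputes everything; UIs are empirical
  2.5th/97.5th percentiles. Attribution re-runs the model with exactly
  one factor's shift active; because combination is multiplicative the
  single-factor rows need not sum to the joint total, and the residual
  is reported explicitly.

**Epidemiological constants are configuration, not findings.** The
source study names its model but prints no relative risks; the defaults
in `default_pathway_params()` (e.g. CVD 1.40 per 5 BMI units, 1.90 per
20 mmHg SBP, 1.25 per mmol/L cholesterol, 0.91 per 7 g/day fiber) are
literature-style placeholders with plausible magnitudes and standard
errors. Nothing in the test suite or acceptance machinery depends on
their values — only on model mechanics (null scenarios, monotonicity,
closed-form agreement, attribution exactness).

## Synthetic world (`synth`)

The generator produces every input table with the structure the
analysis assumes, plus the ground truth needed for recovery tests.

* **Food supply.** 14 major categories with realistic reference amounts
  and energy densities; minor categories at ~8 foods each. Symbol
  nutrients are drawn as log-normal multiples of each food's *applicable
  threshold*: a latent per-nutrient 'high' flag (probability
  `1 - (1 - f)^(1/3)` per nutrient, f = 0.33 the target high-in share)
  selects a component centered at 2.0x the threshold (log-SD 0.30)
  or 0.30x (log-SD 0.40), making classification nearly deterministic
  given the flags and the realized share converge to the target.
  Fruit/vegetable majors are exempt by default. An exact 26% of
  non-exempt minor categories is "covered": their branded products are
  70% healthier-component draws (0.25x thresholds, energy x0.85);
  uncovered categories hold only above-threshold products, so the share
  of high-in foods with an alternative converges to the coverage target.
* **Population.** DRI age-sex demographics (19–30/31–50/51–70/71+ by
  sex), heights N(1.76, 0.07)/N(1.62, 0.065) m, BMI log-normal
  (median 26.5, log-SD 0.17) spanning the under/normal/over/obese
  classes. Each respondent gets two recall days; a day's menu is ~10
  foods drawn by popularity with log-normal gram jitter, then rescaled
  so true daily energy equals predicted TEE x exp(b_i + d_ij) x weekend
  multiplier (1.05 on weekend days). `b_i ~ N(0, 0.06^2)` is the person
  effect; day noise variance is 2.5x the person variance. These log-SDs
  are smaller than real diet-survey variation; they are chosen so that
  Goldberg cutoffs recover planted misreporters (12% under-reporters at
  bias 0.60, 8% over-reporters at 1.50, applied to recorded grams)
  >= 90% of the time, which is the property the plant exists to test.
  Survey weights default to 1 with optional log-normal dispersion.
* **Ground truth.** Usual intake truth per person is
  `TEE x exp(b_i) x E[exp(d)] x E[weekend] x E[R_nutrient]`, with the
  menu nutrient-to-energy ratio expectation `E[R]` estimated once from
  simulated menu days (default 4,000; increase for tighter truth).
  Person-level menu preferences are not modeled: within a world, true
  nutrient composition differs across people only through energy — a
  deliberate simplification that keeps truth analytic.
* **Vital statistics.** Full sex x five-year-band (20–85+) x cause
  cross for CVD, cancer, diabetes, chronic renal failure and liver
  disease; death counts rise with age at cause-specific Gompertz-like
  slopes and are apportioned by largest remainder so they sum exactly
  to the configured total (default 92,845); population declines at
  older ages and sums to its configured total.

What passing tests on this world do **not** show: realistic brand-level
nutrient distributions, person-specific food preferences, seasonal or
weekday menu structure, or real survey weight/replicate designs. They
do show that every mechanical guarantee of the pipeline — thresholds,
strict-reduction matching, weight-preserving substitution, dose
proportionality, variance decomposition, CI calibration under met
assumptions, PIF arithmetic — holds end to end.

## Reporting (`report`)

All printed shares round half away from zero at the surface's printed
precision, and every share re-derives from its own count and total (an
emission-time consistency check). Scenario deltas are computed from
unrounded means and rounded last. `run_full_pipeline` derives every
stage seed from the master seed via independent seed sequences, records
seeds, row counts and a bundle SHA-256 in `manifest.json`, and is
bit-identical under a fixed configuration.

## Problem sizes

Defaults were chosen to make the full run comfortable on one CPU:
2,000 respondents, 2,784 foods, 11,000 branded products, 500 bootstrap
replicates, 10,000 Monte Carlo iterations — about one minute end to
end. The simulation-calibration tests use 200 replicates of a 250-person
population with 200 bootstrap replicates; the dose-proportionality test
averages 200 selection draws on a 2,000-person population.
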