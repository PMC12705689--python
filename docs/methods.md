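# Methods

This note documents the statistical procedures implemented in `triarm`,
the assumptions behind them, the synthetic-data generator that the test
suite exercises them on, and the numerical/design choices that were
genuinely open.

## Trial structure and randomization

The package models a single-site, three-arm parallel trial: two
experimental diets (labelled LCPUFA and HND) against usual care (UC),
1:1:1 allocation, stratified by sex and diabetes status. Allocation
uses permuted blocks within each stratum (default block size equals the
ratio sum, i.e. 3), so per-stratum arm counts differ by at most one
partial block. Household members are co-randomized: the first member of
a household is randomized as a unit and later members copy its arm.
This mirrors the design concern that cohabiting participants would
otherwise contaminate each other's diets; it slightly perturbs marginal
balance, exactly as it does in practice.

## Synthetic-data generator

`synthetic_trial.generate_cohort` draws a cohort of 150 subjects (50 per
arm by default) with demographics typical of an older, overweight
population at risk of steatotic liver disease: age ≈ 64 ± 8 years
(truncated 30–75), BMI ≈ 30 ± 3.5 kg/m² (truncated 25–40), 39% women,
55% with type 2 diabetes, 58% carrying the common PNPLA3 genotype.
Baseline weight is derived from BMI and height so the anthropometry is
internally consistent.

Outcomes are carried as baseline/month-12 pairs. Right-skewed outcomes
(liver fat, triglycerides, CRP, fasting glucose) draw lognormal
baselines parameterized by median and log-SD, matched to the
descriptive scale of such trials (liver fat median 6.4%, log-SD 0.8);
symmetric outcomes (HbA1c, LDL) are Gaussian. The month-12 value is

    Y(12) = Y(0) + direct arm effect + b · (weight change) + household effect + noise,

and the mediator is `weight change = a(arm) + household effect + noise`
with SD 4.5 kg. The defaults plant *total* between-arm differences of
−1.46 (LCPUFA vs UC) and −1.76 (HND vs UC) percentage units liver fat
and −2.77 kg weight (HND vs UC), with a mediator slope b = 0.4 %/kg
that splits each liver-fat effect into a direct and a weight-mediated
component. The liver-fat residual SD is 3 percentage units — the same
value the sample-size calculation assumes — so design arithmetic,
generator, and pipeline all describe one coherent hypothetical trial.

Truncation: baselines are clipped to the outcome's support (liver fat
to [0, 100] %); month-12 values are clipped at zero only for
lognormal-family outcomes, so that with all noise scales set to zero
the generator is exactly additive (several exactness tests rely on
this).

Missingness is applied only to month-12 cells, with probability
logistic in the z-scored baseline BMI and diabetes status
(coefficients 0.5 and 0.3 on the logit scale by default) and an
intercept solved numerically (Brent's method) so the marginal rate hits
the configured target: 14% for liver fat, 6% for other outcomes. Since
the blanking probability depends only on always-observed baseline
fields, the mechanism is missing-at-random by construction.

What the generator does *not* emulate: dropout as a longitudinal
process, measurement error in MRI fat fraction, medication
co-interventions, seasonal/visit effects, or any dependence of
missingness on unobserved values (MNAR). Tests passing on this
generator therefore validate the estimators' statistical properties
under MAR, not robustness to MNAR or to real-world measurement
artefacts.

Household pairs share a random effect on the mediator and on each
outcome change with configurable SD, default 0: no within-pair
correlation is assumed unless requested, since none is documented; the
knob exists so the pair-exclusion sensitivity analysis can be exercised
against a true correlation.

## Imputation (MICE-PMM)

Each incomplete variable is imputed by predictive mean matching inside
a chained-equations sweep. The conditional model regresses the variable
on diet group, BMI, age, sex, diabetes status, and the variable's own
baseline value. Predictions for missing cells use a posterior draw of
the coefficients (σ² from a scaled inverse-chi-square draw, β from its
normal posterior; "type-1" matching), so imputations are proper and
Rubin variances are valid. Each missing cell receives the observed
value of one of the k = 5 donors with nearest predicted values
(k and the 10 chain sweeps are the method's conventional defaults; the
named method itself fixes neither). Binary flags are imputed by PMM on
their 0/1 coding — the donor property keeps them binary without
rounding. m = 20 completions by default. Observed cells are never
modified, and each chain is independently seeded, so stacks are
reproducible bit-for-bit.

When only the analysed outcome's month-12 column is incomplete and all
predictors are fully observed (the common case here), the chain
converges after a single sweep; loops that impute inside bootstrap
resamples exploit this and run a single PMM draw per completion.

## Parametric branch

ANCOVA of the change score on arm indicators plus baseline outcome,
sex, and diabetes status, fitted per completion (statsmodels OLS; the
Monte-Carlo loops use an internal QR least-squares helper pinned to the
statsmodels fit by a unit test). Scalar contrasts are pooled by Rubin's
rules with Barnard–Rubin small-sample degrees of freedom; the 2-df
omnibus arm test uses the D1 multivariate Wald combination with the
Li–Raghunathan–Rubin denominator degrees of freedom. Pairwise
comparisons are *refit* on each two-arm subset (matching the pipeline's
description of "linear models for pairwise comparisons") rather than
read off the three-arm fit; a `refit=False` option extracts them from
the full fit instead, where contrast transitivity is exact. The
pairwise stage runs only when the pooled omnibus test is significant at
α = 0.05; for three groups this gatekeeping keeps the familywise error
at or below the nominal level, which the simulation suite verifies
empirically rather than assumes.

Routing between branches follows a Shapiro–Wilk screen on the ANCOVA
residuals, one W per completion, summarized by the median (the
diagnostic's behaviour under multiple imputation is a convention; the
median is robust to an occasional aberrant completion). The branch is
declared Gaussian only when the summary W strictly exceeds 0.95.

## Nonparametric branch

Covariate adjustment by the residual method: fit the change score on
the covariates with diet group omitted, keep residual + grand-mean
change (location-preserving, so group medians remain on the change
scale). The omnibus test is a tie-corrected Kruskal–Wallis on these
adjusted values; under multiple imputation the per-completion p-values
are combined by their median (a `mean_z` probit alternative is
provided; neither rule is canonical and both behave conservatively in
the shipped null simulations).

Effect sizes are adjusted median differences with
bootstrap-then-impute percentile intervals: resample subjects —
household pairs as whole clusters — then impute each resample
(m = 2 completions per resample at desk scale), average the
per-completion differences of group medians into one replicate, and
take the 2.5/97.5 percentiles over B replicates. The point estimate is
the replicate mean; the p-value inverts the replicate sign fraction,
2·min(frac ≤ 0, frac ≥ 0), clamped to [2/B, 1]. Resamples that lose an
entire arm are redrawn and counted. Desk-scale default is B = 500;
B = 10,000 with m = 20 is selectable where compute allows. The
"adjusted median difference" estimand is a deliberate choice: under
symmetric residuals it coincides with the parametric EMM difference,
so the two branches estimate the same quantity when both are valid.

The per-protocol analogue is a complete-case analysis; on the rank
route pairwise shifts use the Hodges–Lehmann estimator (median of all
pairwise differences) with the rank-sum-inversion (Moses,
normal-approximation) confidence interval.

## Mediation

Linear natural-effects decomposition with weight change as mediator:
a mediator model (weight change ~ arm + covariates) and an outcome
model (liver-fat change ~ arm + weight change + covariates), covariates
being the ANCOVA set plus baseline weight (the covariate set for the
mediation models is an assumption, not a documented fact). NIE = a·b,
NDE = c′, TE = NIE + NDE; in this no-interaction linear case TE equals
the arm coefficient of the no-mediator regression, an identity asserted
in the tests. PM = 100·NIE/TE may be negative or exceed 100%
(inconsistent mediation) and is reported as undefined when |TE| falls
below 1e-10. Percentile intervals come from a subject-level bootstrap;
replicates with |TE| below tolerance are excluded from the PM interval
and counted, with an instability warning above 20% exclusions. An
optional exposure–mediator interaction switches to the counterfactual
formulas evaluated at the reference-arm mediator mean. Under multiple
imputation, NDE/NIE/TE are pooled as means over completions and PM is
recomputed from the pooled components — ratios are never pooled
directly.

## Design and power

Two sample-size routes are provided. Lehr's rule of 16,
`ceil(16/(Δ/σ)²)`, gives 36 per group at (Δ = 2, σ = 3); the exact
noncentral-t iteration (df = 2n − 2, ncp = (Δ/σ)·√(n/2)) gives 37, the
figure a trial would carry forward. The discrepancy is a property of
the formulas, not a bug, and both numbers are exposed; across
standardized differences 0.3–1.5 the two routes differ by at most 2 in
either direction (Lehr's rounded constant 16 overshoots at small
effects, the t correction dominates at large ones). Attrition
inflation is `ceil(n/(1 − rate))`: 37 becomes 50 per group at 25%
dropout. `empirical_power` verifies the design point by direct
simulation.

## Operating-characteristic simulations

`harness.simulate_operating_characteristics` validates, by Monte Carlo:
(i) familywise error of the gatekept pipeline under a global null
(Gaussian change scores, a baseline covariate correlated with change,
n = 50/arm); (ii) power at the design point; (iii) coverage of the
bootstrap-then-impute interval under a zero planted effect with 14%
MAR missingness; (iv) proportion-mediated recovery at a planted 50%.
Problem sizes in the shipped tests (e.g. 200–500 replicates, B = 500,
m = 2–5, chain sweeps 2–3 where a single incomplete variable makes
more redundant) are the package's desk-scale presets, chosen so the
whole suite validates every property at useful Monte-Carlo precision;
each assertion carries a binomial or 3-SE band derived from its own
replicate count.

## Numerical choices and degenerate inputs

- Rank-deficient ANCOVA designs raise an error naming the first aliased
  column; the PMM regression instead warns and uses the minimum-norm
  solution (imputation should not abort a whole stack for a collinear
  dummy).
- Kruskal–Wallis on all-equal samples returns H = 0, p = 1 (the
  tie-correction limit) rather than raising.
- Remission rates with an empty denominator return NaN, not an error.
- All Monte-Carlo components consume `numpy` `SeedSequence`-spawned
  child streams, so every result is reproducible from a single integer
  seed and independent components do not share streams.
- B below 100 for a reported bootstrap CI, m below 2 for Rubin pooling,
  and probabilities outside [0, 1] are rejected at configuration time.

## Known limitations

- No multilevel imputation for household clustering (pairs are handled
  by cluster resampling and by the exclusion sensitivity analysis, not
  by a random-effects imputation model).
- No MNAR sensitivity models; the MAR assumption is structural.
- The bootstrap p-value is percentile-based and shares the percentile
  interval's small-B granularity.
- Mediation assumes no unmeasured mediator–outcome confounding and no
  measurement error in the mediator; no sensitivity analysis for either
  is provided.
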