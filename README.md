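# triarm

Statistical pipeline for a three-arm (1:1:1) randomized dietary trial
with a continuous primary outcome — liver fat measured as MRI
proton-density fat fraction — in adults with type 2 diabetes or
prediabetes. The package is aimed at trial statisticians who want the
complete analysis chain as tested, reusable code: stratified
permuted-block randomization (with co-randomized household pairs),
multiple imputation by chained equations with predictive mean matching
(MICE-PMM), per-imputation ANCOVA pooled by Rubin's rules with an
F-gatekeeping strategy for the three pairwise comparisons, a
nonparametric branch (covariate-adjusted residuals, Kruskal–Wallis,
bootstrap-then-impute median contrasts, Hodges–Lehmann estimation),
regression-based causal mediation, and design/power arithmetic. A
synthetic-trial generator reproduces the statistical structure of such a
trial so every stage can be validated against planted truth.

## The model

For each outcome `Y`, the analysis model is an ANCOVA on the change
score:

    ΔY_i = Y_i(12mo) − Y_i(0)  =  β₀ + β_arm[i] + γ·Y_i(0) + δ·sex_i + ζ·T2D_i + ε_i

Between-arm differences are estimated marginal mean (EMM) differences,
which in this additive model equal arm-coefficient differences. Missing
month-12 values are multiply imputed (m = 20 by default) by PMM; each
scalar contrast Q is pooled over imputations with Rubin's rules,

    Q̄ = mean(Q_j),   T = W + (1 + 1/m)·B,

with W the mean within-imputation variance, B the between-imputation
variance, and Barnard–Rubin degrees of freedom. The 2-df omnibus arm
test uses the multivariate Wald (D1) combination; pairwise contrasts are
released only when the pooled omnibus test is significant (gatekeeping,
which preserves the familywise error rate for three groups). Outcomes
whose ANCOVA residuals fail a Shapiro–Wilk screen (summary W ≤ 0.95)
are instead analysed on covariate-adjusted residuals with a
Kruskal–Wallis test, and effect sizes are reported as adjusted median
differences with percentile intervals from a bootstrap-then-impute
scheme. Mediation of the liver-fat effect by weight change uses the
linear natural-effects decomposition NIE = a·b, NDE = c′,
TE = NIE + NDE, proportion mediated PM = 100·NIE/TE.

## Worked example

```python
from triarm import harness
from triarm.synthetic_trial import GeneratorConfig, generate_cohort, apply_missingness

cfg = GeneratorConfig()                        # 150 subjects, 3 arms
trial = apply_missingness(generate_cohort(cfg, seed=1), cfg, seed=2)
rc = harness.RunConfig(outcomes=("weight",), m=20, seed=7)
report = harness.run_primary_analysis(trial, rc)["weight"]
print(report["branch"], report["global_test"]["p"], report["gate_status"])
for c in report["contrasts"]:
    print(c["label"], round(c["estimate"], 2),
          (round(c["ci_low"], 2), round(c["ci_high"], 2)), round(c["p"], 4))
```

prints

```
parametric 0.0155 released
HND vs LCPUFA -2.91 (-4.97, -0.85) 0.0061
HND vs UC -2.03 (-4.1, 0.03) 0.0533
LCPUFA vs UC 0.91 (-1.13, 2.95) 0.3761
```

The generator plants total weight effects of −2.46 kg for HND vs
LCPUFA, −2.77 kg for HND vs UC, and −0.31 kg for LCPUFA vs UC; on this
seed the pooled omnibus test fires (p = 0.0155), the gate opens, and
all three Rubin-pooled pairwise intervals bracket their planted values
(the HND vs UC interval grazes zero — single-trial noise, the planted
truth sits well inside it). The same entry point routes skew-residual
outcomes down the rank-based branch automatically.

Design arithmetic from the command line:

```bash
triarm power --delta 2 --sd 3          # Lehr: 36, noncentral-t: 37, enrolled: 50
triarm simulate --n-per-arm 50 --seed 1 --out trial.csv
triarm analyze trial.csv --outcome liver_fat --out report.json
```

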