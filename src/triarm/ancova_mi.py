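"""Parametric branch: ANCOVA on change scores, Rubin pooling, gatekeeping.

The primary model regresses the 12-month change (month 12 minus
baseline) on diet group plus baseline covariates (baseline value of the
outcome, sex, diabetes status).  Under multiple imputation the model is
fitted once per completed dataset; scalar contrasts are pooled with
Rubin's rules (Barnard-Rubin degrees of freedom) and the 2-df omnibus
group test is combined with the multivariate Wald (D1) statistic.
Pairwise comparisons are performed only when the pooled omnibus test is
significant, which preserves the familywise error rate for three
groups.  Residual normality is screened with Shapiro-Wilk; a summary
W above 0.95 routes the outcome down this parametric branch, otherwise
the rank-based branch in :mod:`triarm.nonparam` is used.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from triarm.errors import ConfigError
from triarm.mice_pmm import ImputedStack

__all__ = [
    "AnalysisSpec",
    "AncovaFit",
    "PooledContrast",
    "GlobalTest",
    "NormalityCheck",
    "fit_ancova",
    "pool_rubin",
    "pooled_global_test",
    "gatekeep_pairwise",
    "residual_normality",
]


@dataclass(frozen=True)
class AnalysisSpec:
    """One outcome's analysis contract.

    outcome: base name; the change score is <outcome>_m12 - <outcome>_m0.
    covariates: baseline adjustment set (column names; "baseline" is
        replaced by <outcome>_m0, "sex"/"t2d" enter as indicators).
    reference: reference arm for contrasts.
    """

    outcome: str = "liver_fat"
    covariates: tuple[str, ...] = ("baseline", "sex", "t2d")
    reference: str = "UC"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")

    def change(self, table: pd.DataFrame) -> pd.Series:
        return table[f"{self.outcome}_m12"] - table[f"{self.outcome}_m0"]

    def design(self, table: pd.DataFrame, with_arm: bool = True,
               ) -> tuple[np.ndarray, list[str], list[str]]:
        """Design matrix, column names, and non-reference arm levels."""
        cols: list[np.ndarray] = [np.ones(len(table))]
        names = ["const"]
        arms: list[str] = []
        if with_arm:
            levels = [a for a in pd.unique(table["arm"])
                      if a != self.reference]
            levels.sort()
            for a in levels:
                cols.append((table["arm"] == a).to_numpy(dtype=float))
                names.append(f"arm[{a}]")
            arms = levels
        for c in self.covariates:
            if c == "baseline":
                cols.append(table[f"{self.outcome}_m0"].to_numpy(dtype=float))
                names.append(f"{self.outcome}_m0")
            elif c == "sex":
                cols.append((table["sex"] == "woman").to_numpy(dtype=float))
                names.append("sex[woman]")
            else:
                cols.append(table[c].to_numpy(dtype=float))
                names.append(c)
        return np.column_stack(cols), names, arms


@dataclass
class AncovaFit:
    """A single-dataset ANCOVA fit with contrast accessors."""

    params: pd.Series
    cov: pd.DataFrame
    resid: np.ndarray
    df_resid: int
    arms: list[str]
    reference: str

    def contrast(self, arm1: str, arm2: str) -> tuple[float, float]:
        """EMM difference arm1 - arm2 and its squared SE.

        Because the model is additive, the estimated marginal-mean
        difference equals the arm-coefficient difference.
        """
        def coef_name(a: str) -> str | None:
            return None if a == self.reference else f"arm[{a}]"

        n1, n2 = coef_name(arm1), coef_name(arm2)
        est = ((self.params[n1] if n1 else 0.0)
               - (self.params[n2] if n2 else 0.0))
        var = 0.0
        if n1:
            var += self.cov.loc[n1, n1]
        if n2:
            var += self.cov.loc[n2, n2]
        if n1 and n2:
            var -= 2 * self.cov.loc[n1, n2]
        return float(est), float(var)

    def arm_wald(self) -> tuple[np.ndarray, np.ndarray]:
        """Arm-coefficient vector and covariance block (omnibus test input)."""
        names = [f"arm[{a}]" for a in self.arms]
        return (self.params[names].to_numpy(),
                self.cov.loc[names, names].to_numpy())

    def global_f(self) -> tuple[float, float, int, int]:
        """Exact single-dataset F-test of no arm effect: (F, p, df1, df2)."""
        q, v = self.arm_wald()
        k = len(q)
        f = float(q @ np.linalg.solve(v, q)) / k
        return f, float(stats.f.sf(f, k, self.df_resid)), k, self.df_resid


def fit_ancova(table: pd.DataFrame, spec: AnalysisSpec) -> AncovaFit:
    """Least-squares ANCOVA of the change score on arm + covariates."""
    present = pd.unique(table["arm"])
    if len(present) < 2:
        raise ConfigError("at least two arms required for ANCOVA")
    X, names, arms = spec.design(table)
    y = spec.change(table).to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ConfigError("ANCOVA requires a completed table (no missing "
                          "values in modeled columns)")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the aliased column for the error message
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, :j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                raise ConfigError(f"design column {names[j]!r} is aliased")
        raise ConfigError("rank-deficient design")
    res = sm.OLS(y, X).fit()
    return AncovaFit(
        params=pd.Series(res.params, index=names),
        cov=pd.DataFrame(res.cov_params(), index=names, columns=names),
        resid=np.asarray(res.resid),
        df_resid=int(res.df_resid),
        arms=arms,
        reference=spec.reference,
    )


@dataclass(frozen=True)
class PooledContrast:
    """A Rubin-pooled pairwise arm comparison."""

    label: str
    qbar: float
    w_within: float
    b_between: float
    t_total: float
    df: float
    ci_low: float
    ci_high: float
    p: float
    m: int


def pool_rubin(estimates: Sequence[float], variances: Sequence[float],
               label: str = "", dfcom: float | None = None,
               alpha: float = 0.05) -> PooledContrast:
    """Rubin's rules for a scalar estimand.

    qbar = mean estimate; W = mean within variance; B = between variance;
    T = W + (1 + 1/m) B.  Degrees of freedom follow Barnard-Rubin when
    the complete-data df is supplied, else the classic large-sample form.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ConfigError("estimates and variances must be equal-length 1-D")
    m = len(q)
    if m < 2:
        raise ConfigError("Rubin pooling needs m >= 2 imputations")
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t = w + (1 + 1 / m) * b
    if t <= 0:
        raise ConfigError("total variance must be positive")
    lam = (1 + 1 / m) * b / t
    if lam <= 0:
        df = float(dfcom) if dfcom is not None else np.inf
    else:
        df_old = (m - 1) / lam**2
        if dfcom is None:
            df = df_old
        else:
            df_obs = (dfcom + 1) / (dfcom + 3) * dfcom * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    se = np.sqrt(t)
    tcrit = stats.t.ppf(1 - alpha / 2, df) if np.isfinite(df) else stats.norm.ppf(1 - alpha / 2)
    pval = (2 * stats.t.sf(abs(qbar) / se, df) if np.isfinite(df)
            else 2 * stats.norm.sf(abs(qbar) / se))
    return PooledContrast(label=label, qbar=qbar, w_within=w, b_between=b,
                          t_total=t, df=float(df),
                          ci_low=float(qbar - tcrit * se),
                          ci_high=float(qbar + tcrit * se),
                          p=float(pval), m=m)


@dataclass(frozen=True)
class GlobalTest:
    """Pooled omnibus test of any between-arm difference (D1 combination)."""

    statistic: float
    df1: float
    df2: float
    p: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def _fit_stack(stack: ImputedStack, spec: AnalysisSpec) -> list[AncovaFit]:
    return [fit_ancova(t, spec) for t in stack.tables]


def pooled_global_test(stack: ImputedStack, spec: AnalysisSpec,
                       fits: list[AncovaFit] | None = None) -> GlobalTest:
    """Multivariate Wald (D1) combination of the k-df arm-effect test."""
    fits = fits if fits is not None else _fit_stack(stack, spec)
    qs, vs = zip(*(f.arm_wald() for f in fits))
    k = len(qs[0])
    if k < 2:
        raise ConfigError("omnibus test needs at least 3 arm levels")
    m = len(fits)
    Q = np.vstack(qs)
    qbar = Q.mean(axis=0)
    wbar = np.mean(vs, axis=0)
    if m == 1:
        f, p, df1, df2 = fits[0].global_f()
        return GlobalTest(statistic=f, df1=df1, df2=float(df2), p=p,
                          alpha=spec.alpha)
    B = np.cov(Q.T, ddof=1)
    r1 = max((1 + 1 / m) * np.trace(B @ np.linalg.inv(wbar)) / k, 1e-12)
    d1 = float(qbar @ np.linalg.solve(wbar, qbar)) / (k * (1 + r1))
    t = k * (m - 1)
    if t > 4:
        df2 = 4 + (t - 4) * (1 + (1 - 2 / t) / r1) ** 2
    else:
        df2 = t * (1 + 1 / k) * (1 + 1 / r1) ** 2 / 2
    p = float(stats.f.sf(d1, k, df2))
    return GlobalTest(statistic=d1, df1=k, df2=float(df2), p=p,
                      alpha=spec.alpha)


@dataclass
class GatekeptPairwise:
    """Pairwise contrasts released only after a significant omnibus test."""

    status: str  # "released" or "gatekept"
    contrasts: list[PooledContrast]


def gatekeep_pairwise(global_test: GlobalTest, stack: ImputedStack,
                      spec: AnalysisSpec, refit: bool = True,
                      fits: list[AncovaFit] | None = None,
                      ) -> GatekeptPairwise:
    """Release the three pairwise comparisons only if the omnibus fires.

    With ``refit=True`` (default) each pair is re-estimated on the
    two-arm subset with the same covariates, then Rubin-pooled; with
    ``refit=False`` the contrasts are read off the full three-arm fit.
    """
    if not global_test.significant:
        return GatekeptPairwise(status="gatekept", contrasts=[])
    arms = sorted(pd.unique(stack.tables[0]["arm"]))
    pairs = list(itertools.combinations(arms, 2))
    out: list[PooledContrast] = []
    dfcom = None
    for a1, a2 in pairs:
        ests, var = [], []
        for i, t in enumerate(stack.tables):
            if refit:
                sub = t[t["arm"].isin([a1, a2])]
                sub_spec = AnalysisSpec(outcome=spec.outcome,
                                        covariates=spec.covariates,
                                        reference=a2, alpha=spec.alpha)
                fit = fit_ancova(sub, sub_spec)
            else:
                fit = (fits[i] if fits is not None
                       else fit_ancova(t, spec))
            e, v = fit.contrast(a1, a2)
            ests.append(e)
            var.append(v)
            dfcom = fit.df_resid
        out.append(pool_rubin(ests, var, label=f"{a1} vs {a2}",
                              dfcom=dfcom, alpha=spec.alpha))
    return GatekeptPairwise(status="released", contrasts=out)


@dataclass(frozen=True)
class NormalityCheck:
    """Shapiro-Wilk residual diagnostic summarised over imputations."""

    w_per_imputation: tuple[float, ...]
    w_summary: float
    gaussian: bool
    threshold: float = 0.95


def residual_normality(stack: ImputedStack, spec: AnalysisSpec,
                       threshold: float = 0.95,
                       fits: list[AncovaFit] | None = None,
                       ) -> NormalityCheck:
    """Shapiro-Wilk W on ANCOVA residuals, summarised by the median.

    The branch is called Gaussian only when the summary W strictly
    exceeds the threshold (default 0.95).
    """
    fits = fits if fits is not None else _fit_stack(stack, spec)
    ws = []
    for f in fits:
        if len(f.resid) < 3:
            raise ConfigError("Shapiro-Wilk undefined for n < 3")
        ws.append(float(stats.shapiro(f.resid).statistic))
    w_summary = float(np.median(ws))
    return NormalityCheck(w_per_imputation=tuple(ws), w_summary=w_summary,
                          gaussian=w_summary > threshold,
                          threshold=threshold)
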