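"""Nonparametric branch: adjusted-residual rank tests and median contrasts.

When ANCOVA residuals fail the normality screen, group differences are
assessed on covariate-adjusted residuals (the residual method of Willett:
fit the change score on the covariates with diet group omitted, keep the
residuals) with a Kruskal-Wallis test, and pairwise effect sizes are
reported as adjusted median differences with percentile confidence
intervals from a bootstrap-then-impute scheme: resample subjects (or
household clusters), impute each resample a small number of times, and
average the per-completion adjusted median differences into one
bootstrap replicate.  The per-protocol complete-case analogue uses the
Hodges-Lehmann estimator with a rank-sum-inversion confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from triarm._linmod import fast_ols
from triarm.errors import ConfigError
from triarm.mice_pmm import ImputedStack, pmm_match
from triarm.ancova_mi import AnalysisSpec

__all__ = [
    "MedianContrast",
    "adjusted_residuals",
    "adjusted_median_difference",
    "kruskal_wallis",
    "mi_kw_test",
    "boot_impute_median_contrasts",
    "hodges_lehmann",
]


def adjusted_residuals(table: pd.DataFrame, spec: AnalysisSpec) -> pd.Series:
    """Covariate-adjusted change values (location preserved).

    Fits change ~ covariates with NO group term and returns residual +
    grand-mean change, so the adjusted values live on the original
    change scale and group medians remain interpretable.
    """
    X, _, _ = spec.design(table, with_arm=False)
    y = spec.change(table).to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ConfigError("adjusted_residuals requires a completed table")
    fit = fast_ols(X, y)
    return pd.Series(fit.resid + y.mean(), index=table.index,
                     name=f"{spec.outcome}_adjusted_change")


def adjusted_median_difference(table: pd.DataFrame, spec: AnalysisSpec,
                               arm1: str, arm2: str) -> float:
    """Plug-in difference of group medians of adjusted change values."""
    adj = adjusted_residuals(table, spec)
    arms = table["arm"]
    return float(np.median(adj[arms == arm1]) - np.median(adj[arms == arm2]))


def kruskal_wallis(values, group_labels) -> dict:
    """Tie-corrected Kruskal-Wallis H and chi-square p-value.

    All-equal samples return H = 0 (the tie-correction limit) rather
    than raising.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ConfigError("Kruskal-Wallis needs >= 2 nonempty groups")
    if np.all(values == values[0]):
        return {"H": 0.0, "p": 1.0, "df": len(groups) - 1}
    h, p = stats.kruskal(*groups)
    return {"H": float(h), "p": float(p), "df": len(groups) - 1}


def mi_kw_test(stack: ImputedStack, spec: AnalysisSpec,
               rule: str = "median") -> dict:
    """Kruskal-Wallis on adjusted residuals, combined over imputations.

    ``rule="median"`` (default) reports the median per-imputation
    p-value; ``rule="mean_z"`` averages probit-transformed p-values and
    back-transforms, a smoother alternative.  The combination rule for
    rank tests under multiple imputation is a convention, not a theorem;
    both are conservative in the simulations shipped with the tests.
    """
    ps, hs = [], []
    for t in stack.tables:
        adj = adjusted_residuals(t, spec)
        res = kruskal_wallis(adj.to_numpy(), t["arm"].to_numpy())
        ps.append(res["p"])
        hs.append(res["H"])
    ps_arr = np.asarray(ps)
    if rule == "median":
        pooled = float(np.median(ps_arr))
    elif rule == "mean_z":
        z = stats.norm.isf(np.clip(ps_arr, 1e-300, 1.0))
        pooled = float(stats.norm.sf(z.mean()))
    else:
        raise ConfigError(f"unknown combination rule {rule!r}")
    return {"p": pooled, "rule": rule,
            "per_imputation_p": ps, "per_imputation_H": hs,
            "H_median": float(np.median(hs))}


@dataclass(frozen=True)
class MedianContrast:
    """Adjusted median difference with bootstrap percentile CI."""

    label: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    B: int
    m_per_bootstrap: int
    seed: int | None
    n_redrawn: int = 0


def boot_impute_median_contrasts(table: pd.DataFrame, spec: AnalysisSpec,
                                 B: int = 500, m_per_bootstrap: int = 2,
                                 k_donors: int = 5, seed: int | None = None,
                                 predictors: tuple[str, ...] = (
                                     "arm", "bmi_m0", "age", "sex", "t2d"),
                                 ) -> list[MedianContrast]:
    """Bootstrap-then-impute percentile CIs for adjusted median differences.

    For each of B resamples of subjects (household pairs resampled as
    whole clusters when a ``household_id`` column is present): impute the
    outcome's missing month-12 values ``m_per_bootstrap`` times by PMM,
    compute the adjusted median difference for every arm pair in each
    completion, and average over completions to form one replicate.  The
    point estimate is the replicate mean, the CI the 2.5/97.5 percentile
    interval, and the p-value the inverted sign fraction
    2*min(frac <= 0, frac >= 0) clamped to [2/B, 1].

    Resamples that lose an entire arm are redrawn (counted in the
    result).  Missingness is assumed confined to the analyzed outcome's
    month-12 column; the PMM predictors are always-observed baseline
    columns, so no chained sweeps are needed.
    """
    if B < 100:
        raise ConfigError("B must be at least 100 for a reported CI")
    rng = np.random.default_rng(seed)
    n = len(table)
    y0 = table[f"{spec.outcome}_m0"].to_numpy(dtype=float)
    y12 = table[f"{spec.outcome}_m12"].to_numpy(dtype=float)
    miss = np.isnan(y12)
    if np.isnan(y0).any():
        raise ConfigError("baseline outcome must be complete")

    # imputation design (diet group + baseline covariates + baseline value)
    imp_cols = [np.ones(n)]
    arm_levels = sorted(pd.unique(table["arm"]))
    for a in arm_levels[1:]:
        imp_cols.append((table["arm"] == a).to_numpy(dtype=float))
    for c in predictors:
        if c == "arm" or c not in table.columns:
            continue
        v = table[c]
        if v.dtype == object:
            for lev in sorted(pd.unique(v))[1:]:
                imp_cols.append((v == lev).to_numpy(dtype=float))
        else:
            imp_cols.append(v.to_numpy(dtype=float))
    imp_cols.append(y0)
    X_imp = np.column_stack(imp_cols)

    Z_adj, _, _ = spec.design(table, with_arm=False)
    arms = table["arm"].to_numpy()
    pairs = [(a1, a2) for i, a1 in enumerate(arm_levels)
             for a2 in arm_levels[i + 1:]]

    # cluster resampling units
    if "household_id" in table.columns:
        hh = table["household_id"].to_numpy(dtype=float, na_value=np.nan)
        clusters: list[np.ndarray] = []
        seen: dict = {}
        for pos, h in enumerate(hh):
            if np.isnan(h):
                clusters.append(np.array([pos]))
            elif h in seen:
                clusters[seen[h]] = np.append(clusters[seen[h]], pos)
            else:
                seen[h] = len(clusters)
                clusters.append(np.array([pos]))
    else:
        clusters = [np.array([pos]) for pos in range(n)]
    n_cl = len(clusters)

    reps = {pair: np.empty(B) for pair in pairs}
    n_redrawn = 0
    for b in range(B):
        for _attempt in range(200):
            pick = rng.integers(n_cl, size=n_cl)
            idx = np.concatenate([clusters[c] for c in pick])
            if len(np.unique(arms[idx])) == len(arm_levels):
                break
            n_redrawn += 1
        else:
            raise ConfigError("could not draw a resample containing all arms")
        y0_b, y12_b, miss_b = y0[idx], y12[idx], miss[idx]
        Xi_b, Z_b, arms_b = X_imp[idx], Z_adj[idx], arms[idx]
        acc = {pair: 0.0 for pair in pairs}
        for _j in range(m_per_bootstrap):
            y_fill = y12_b.copy()
            if miss_b.any():
                vals, _ = pmm_match(y12_b[~miss_b], Xi_b[~miss_b],
                                    Xi_b[miss_b], k_donors, rng)
                y_fill[miss_b] = vals
            change = y_fill - y0_b
            beta, *_ = np.linalg.lstsq(Z_b, change, rcond=None)
            adj = change - Z_b @ beta + change.mean()
            for a1, a2 in pairs:
                acc[(a1, a2)] += (np.median(adj[arms_b == a1])
                                  - np.median(adj[arms_b == a2]))
        for pair in pairs:
            reps[pair][b] = acc[pair] / m_per_bootstrap

    out = []
    for a1, a2 in pairs:
        r = reps[(a1, a2)]
        frac_le = np.mean(r <= 0)
        frac_ge = np.mean(r >= 0)
        p = min(max(2 * min(frac_le, frac_ge), 2 / B), 1.0)
        out.append(MedianContrast(
            label=f"{a1} vs {a2}",
            estimate=float(r.mean()),
            ci_low=float(np.percentile(r, 2.5)),
            ci_high=float(np.percentile(r, 97.5)),
            p=float(p), B=B, m_per_bootstrap=m_per_bootstrap,
            seed=seed, n_redrawn=n_redrawn))
    return out


def hodges_lehmann(x, y, confidence: float = 0.95) -> dict:
    """Hodges-Lehmann shift estimate for x - y with a rank-sum CI.

    The estimate is the median of all pairwise differences x_i - y_j;
    the confidence interval inverts the Wilcoxon rank-sum test via the
    normal approximation to the Mann-Whitney count (Moses method).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ConfigError("both samples must be nonempty")
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    est = float(np.median(diffs))
    nm = len(diffs)
    z = stats.norm.ppf((1 + confidence) / 2)
    c = len(x) * len(y) / 2 - z * np.sqrt(
        len(x) * len(y) * (len(x) + len(y) + 1) / 12.0)
    k = max(int(np.floor(c)), 0)
    lo = float(diffs[k]) if k < nm else float(diffs[0])
    hi = float(diffs[nm - 1 - k]) if k < nm else float(diffs[-1])
    return {"estimate": est, "ci_low": lo, "ci_high": hi,
            "confidence": confidence}
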