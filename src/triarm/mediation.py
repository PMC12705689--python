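"""Regression-based causal mediation: weight change as mediator.

For a two-arm comparison the linear no-interaction decomposition uses
two models sharing the baseline covariate set of the primary ANCOVA
(baseline outcome, sex, diabetes status) plus baseline weight:

* mediator model:  weight_change ~ arm + covariates        (slope a)
* outcome model:   outcome_change ~ arm + weight_change + covariates
                                                           (b and c')

Natural indirect effect NIE = a*b, natural direct effect NDE = c', and
the total effect TE = a*b + c' equals the arm coefficient of the
outcome model without the mediator (an algebraic identity in the
linear case).  Proportion mediated PM = 100 * NIE / TE, which may be
negative or exceed 100% under inconsistent mediation; it is undefined
when |TE| is below tolerance.  Confidence intervals come from a
subject-level percentile bootstrap.  An optional exposure-mediator
interaction term switches to the counterfactual formulas evaluated at
the reference-arm mediator mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from triarm.ancova_mi import AnalysisSpec
from triarm.errors import ConfigError
from triarm.mice_pmm import ImputedStack

__all__ = [
    "MediationEstimates",
    "fit_mediation",
    "bootstrap_mediation_ci",
    "pooled_mediation",
]

_TE_TOL = 1e-10


@dataclass
class MediationEstimates:
    """NDE/NIE/TE decomposition with proportion mediated."""

    label: str
    nde: float
    nie: float
    te: float
    pm_percent: float | None  # None when |TE| is below tolerance
    a: float
    b: float
    c_prime: float
    ci: dict = field(default_factory=dict)
    n_excluded_reps: int = 0
    warning: str | None = None


def _design(table: pd.DataFrame, spec: AnalysisSpec, treated: str,
            mediator: str | None, interaction: bool,
            ) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table))]
    names = ["const"]
    z = (table["arm"] == treated).to_numpy(dtype=float)
    cols.append(z)
    names.append("arm")
    if mediator is not None:
        mvals = table[mediator].to_numpy(dtype=float)
        cols.append(mvals)
        names.append("mediator")
        if interaction:
            cols.append(z * mvals)
            names.append("arm:mediator")
    for c in spec.covariates:
        if c == "baseline":
            cols.append(table[f"{spec.outcome}_m0"].to_numpy(dtype=float))
            names.append(f"{spec.outcome}_m0")
        elif c == "sex":
            cols.append((table["sex"] == "woman").to_numpy(dtype=float))
            names.append("sex[woman]")
        else:
            cols.append(table[c].to_numpy(dtype=float))
            names.append(c)
    if "weight_m0" in table.columns and spec.outcome != "weight":
        cols.append(table["weight_m0"].to_numpy(dtype=float))
        names.append("weight_m0")
    return np.column_stack(cols), names


def _decompose(Xm: np.ndarray, Xy: np.ndarray, y: np.ndarray,
               mvals: np.ndarray, z: np.ndarray, interaction: bool,
               ) -> tuple[float, float, float, float, float, float]:
    """(a, b, c', nde, nie, te) from the two fitted linear models.

    Column layout: Xm = [const, arm, covs]; Xy = [const, arm, mediator,
    (arm:mediator,) covs].
    """
    a = float(np.linalg.lstsq(Xm, mvals, rcond=None)[0][1])
    beta_y = np.linalg.lstsq(Xy, y, rcond=None)[0]
    c_prime = float(beta_y[1])
    b = float(beta_y[2])
    if interaction:
        theta3 = float(beta_y[3])
        # counterfactual formulas evaluated at the reference-arm
        # mediator mean (linear models, continuous mediator)
        m_ref = float(mvals[z == 0].mean())
        nde = c_prime + theta3 * m_ref
        nie = (b + theta3) * a
    else:
        nde = c_prime
        nie = a * b
    return a, b, c_prime, nde, nie, nde + nie


def _arrays(table: pd.DataFrame, spec: AnalysisSpec,
            arm_pair: tuple[str, str], mediator: str, interaction: bool,
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                       np.ndarray]:
    treated, _ = arm_pair
    sub = table[table["arm"].isin(arm_pair)]
    if sub["arm"].nunique() != 2:
        raise ConfigError(f"arms {arm_pair} not both present")
    y = spec.change(sub).to_numpy(dtype=float)
    mvals = sub[mediator].to_numpy(dtype=float)
    if np.isnan(y).any() or np.isnan(mvals).any():
        raise ConfigError("mediation requires observed or imputed outcome "
                          "and mediator")
    Xm, _ = _design(sub, spec, treated, mediator=None, interaction=False)
    Xy, _ = _design(sub, spec, treated, mediator=mediator,
                    interaction=interaction)
    z = (sub["arm"] == treated).to_numpy(dtype=float)
    return Xm, Xy, y, mvals, z


def fit_mediation(table: pd.DataFrame, spec: AnalysisSpec,
                  arm_pair: tuple[str, str], mediator: str = "weight_change",
                  interaction: bool = False) -> MediationEstimates:
    """Point estimates of NDE/NIE/TE/PM for treated-vs-reference arms.

    ``arm_pair = (treated, reference)``; effects are expressed as
    treated minus reference on the outcome-change scale.
    """
    treated, ref = arm_pair
    Xm, Xy, y, mvals, z = _arrays(table, spec, arm_pair, mediator,
                                  interaction)
    a, b, c_prime, nde, nie, te = _decompose(Xm, Xy, y, mvals, z,
                                             interaction)
    pm = 100.0 * nie / te if abs(te) > _TE_TOL else None
    return MediationEstimates(label=f"{treated} vs {ref}", nde=nde, nie=nie,
                              te=te, pm_percent=pm, a=a, b=b,
                              c_prime=c_prime)


def bootstrap_mediation_ci(table: pd.DataFrame, spec: AnalysisSpec,
                           arm_pair: tuple[str, str], reps: int = 500,
                           seed: int | None = None,
                           mediator: str = "weight_change",
                           interaction: bool = False) -> MediationEstimates:
    """Subject-level percentile bootstrap CIs for NDE/NIE/TE/PM.

    Replicates whose |TE| falls below tolerance are excluded from the PM
    interval and counted; more than 20% exclusions flags the PM interval
    as unstable.
    """
    if reps < 200:
        raise ConfigError("reps must be at least 200")
    point = fit_mediation(table, spec, arm_pair, mediator, interaction)
    rng = np.random.default_rng(seed)
    Xm, Xy, y, mvals, z = _arrays(table, spec, arm_pair, mediator,
                                  interaction)
    n = len(y)
    draws = {"nde": [], "nie": [], "te": [], "pm": []}
    excluded = 0
    for _ in range(reps):
        idx = rng.integers(n, size=n)
        zb = z[idx]
        if zb.min() == zb.max():  # an arm vanished from the resample
            continue
        _, _, _, nde, nie, te = _decompose(Xm[idx], Xy[idx], y[idx],
                                           mvals[idx], zb, interaction)
        draws["nde"].append(nde)
        draws["nie"].append(nie)
        draws["te"].append(te)
        if abs(te) > _TE_TOL:
            draws["pm"].append(100.0 * nie / te)
        else:
            excluded += 1
    ci = {}
    for key, vals in draws.items():
        if vals:
            arr = np.asarray(vals)
            ci[key] = (float(np.percentile(arr, 2.5)),
                       float(np.percentile(arr, 97.5)))
    point.ci = ci
    point.n_excluded_reps = excluded
    if excluded > 0.2 * reps:
        point.warning = "unstable-PM: >20% of replicates had |TE| ~ 0"
    return point


def pooled_mediation(stack: ImputedStack, spec: AnalysisSpec,
                     arm_pair: tuple[str, str],
                     mediator: str = "weight_change") -> MediationEstimates:
    """Mediation under MI: fit per completion, Rubin-pool the components.

    NDE/NIE/TE are pooled as means over completions (Rubin point rule);
    PM is recomputed from the pooled components rather than pooling the
    per-completion ratios, which are unstable when TE is near zero.
    """
    fits = [fit_mediation(t, spec, arm_pair, mediator)
            for t in stack.tables]
    nde = float(np.mean([f.nde for f in fits]))
    nie = float(np.mean([f.nie for f in fits]))
    te = nde + nie
    pm = 100.0 * nie / te if abs(te) > _TE_TOL else None
    out = MediationEstimates(label=fits[0].label, nde=nde, nie=nie, te=te,
                             pm_percent=pm,
                             a=float(np.mean([f.a for f in fits])),
                             b=float(np.mean([f.b for f in fits])),
                             c_prime=float(np.mean([f.c_prime for f in fits])))
    return out
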