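"""Synthetic three-arm dietary-trial generator.

Emulates the statistical structure the downstream pipeline assumes: a
150-subject 1:1:1 trial (arms LCPUFA, HND, UC) with stratified
permuted-block randomization by sex and diabetes status, co-randomized
household pairs, skewed baseline distributions for liver fat /
triglycerides / CRP, an additive treatment effect on the 12-month change
that is partly transmitted through weight change (the mediator path),
and missing-at-random blanking of month-12 values driven by observed
baseline covariates.

Default effect sizes are calibrated to the trial report: total
between-arm differences of about -1.46 (LCPUFA vs UC) and -1.76 (HND vs
UC) percentage units liver fat, -2.77 kg weight for HND vs UC, with a
mediator-to-liver-fat slope of 0.4 %/kg splitting each total effect into
a direct and a weight-mediated component.  Liver fat month-12 values are
missing at a 14% marginal rate, other outcomes at about 6%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from triarm.errors import ConfigError

__all__ = [
    "BaselineSpec",
    "ArmEffectSpec",
    "GeneratorConfig",
    "DEFAULT_EFFECTS",
    "generate_cohort",
    "assign_arms",
    "apply_missingness",
    "write_trial_csv",
]

ARM_LABELS = ("LCPUFA", "HND", "UC")

#: outcomes carried as <name>_m0 / <name>_m12 column pairs
OUTCOME_ORDER = ("liver_fat", "weight", "glucose", "hba1c", "ldl",
                 "triglycerides", "crp")


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline distribution of one outcome.

    family ``"normal"``: loc = mean, scale = SD.
    family ``"lognormal"``: loc = median on the natural scale, scale = SD
    of the log (so values are loc * exp(scale * Z)).
    """

    family: str
    loc: float
    scale: float

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ConfigError(f"unknown baseline family {self.family!r}")
        if self.scale < 0:
            raise ConfigError("baseline scale must be non-negative")
        if self.family == "lognormal" and self.loc <= 0:
            raise ConfigError("lognormal median must be positive")


@dataclass(frozen=True)
class ArmEffectSpec:
    """Planted per-arm effects.

    effects: additive *direct* effect on the 12-month change of each
    outcome (outcome units); the realised total arm effect on an outcome
    with mediator slope b is ``effects[o] + b * mediator_effect_a``.
    mediator_effect_a: arm effect on weight change (kg).
    """

    arm: str
    effects: Mapping[str, float] = field(default_factory=dict)
    mediator_effect_a: float = 0.0


# Direct effects chosen so that, with mediator slope b = 0.4 %/kg on liver
# fat, the planted TOTAL arm differences reproduce the reported contrasts
# (liver fat: HND-UC = -1.76, LCPUFA-UC = -1.46; weight: HND-UC = -2.77).
DEFAULT_EFFECTS = (
    ArmEffectSpec("LCPUFA", effects={
        "liver_fat": 0.250, "glucose": -0.36, "hba1c": 0.36,
        "ldl": -0.28, "triglycerides": -0.16, "crp": -0.62,
    }, mediator_effect_a=-2.15),
    ArmEffectSpec("HND", effects={
        "liver_fat": 0.934, "glucose": -0.60, "hba1c": -1.33,
        "ldl": -0.30, "triglycerides": -0.29, "crp": -0.88,
    }, mediator_effect_a=-4.61),
    ArmEffectSpec("UC", effects={
        "liver_fat": 1.586, "glucose": -0.22, "hba1c": 0.82,
        "ldl": -0.01, "triglycerides": 0.08, "crp": -0.40,
    }, mediator_effect_a=-1.84),
)

_DEFAULT_BASELINES: dict[str, BaselineSpec] = {
    "liver_fat": BaselineSpec("lognormal", 6.4, 0.8),
    "glucose": BaselineSpec("lognormal", 6.7, 0.17),
    "hba1c": BaselineSpec("normal", 41.0, 8.0),
    "ldl": BaselineSpec("normal", 3.0, 1.1),
    "triglycerides": BaselineSpec("lognormal", 1.3, 0.4),
    "crp": BaselineSpec("lognormal", 1.3, 1.0),
}

_DEFAULT_RESIDUAL_SD: dict[str, float] = {
    "liver_fat": 3.0, "glucose": 0.8, "hba1c": 3.5,
    "ldl": 0.55, "triglycerides": 0.6, "crp": 1.0,
}

_DEFAULT_MISSINGNESS: dict[str, float] = {
    "liver_fat": 0.14, "weight": 0.06, "glucose": 0.06, "hba1c": 0.06,
    "ldl": 0.06, "triglycerides": 0.06, "crp": 0.06,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Trial-generator configuration; defaults mirror the trial design."""

    n_per_arm: int = 50
    allocation: tuple[int, ...] = (1, 1, 1)
    strata: tuple[str, ...] = ("sex", "t2d")
    baselines: Mapping[str, BaselineSpec] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINES))
    residual_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RESIDUAL_SD))
    mediator_to_outcome_b: Mapping[str, float] = field(
        default_factory=lambda: {"liver_fat": 0.4})
    mediator_sd: float = 4.5
    missingness_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISSINGNESS))
    mar_dependence: Mapping[str, float] = field(
        default_factory=lambda: {"bmi_m0": 0.5, "t2d": 0.3})
    n_household_pairs: int = 4
    household_sd: float = 0.0
    block_size: int | None = None
    prop_women: float = 0.39
    prop_t2d: float = 0.55
    prop_pnpla3_cc: float = 0.58

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ConfigError("n_per_arm must be at least 2")
        if any(r <= 0 for r in self.allocation):
            raise ConfigError("allocation ratios must be positive")
        for name, sd in self.residual_sd.items():
            if sd < 0:
                raise ConfigError(f"residual SD for {name} must be >= 0")
        if self.mediator_sd < 0 or self.household_sd < 0:
            raise ConfigError("mediator_sd and household_sd must be >= 0")
        for name, r in self.missingness_rates.items():
            if not 0 <= r <= 1:
                raise ConfigError(
                    f"missingness rate for {name} must lie in [0, 1]")
        if 2 * self.n_household_pairs > self.total_n:
            raise ConfigError("household pairs exceed the cohort size")

    @property
    def total_n(self) -> int:
        return self.n_per_arm * sum(self.allocation)


def _noise_free(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of config with every stochastic scale set to zero (testing aid)."""
    return replace(
        config,
        residual_sd={k: 0.0 for k in config.residual_sd},
        mediator_sd=0.0,
        household_sd=0.0,
    )


def assign_arms(table: pd.DataFrame,
                strata_fields: Sequence[str] = ("sex", "t2d"),
                ratio: Sequence[int] = (1, 1, 1),
                block_size: int | None = None,
                labels: Sequence[str] = ARM_LABELS,
                seed: int = 0,
                household_col: str = "household_id") -> pd.DataFrame:
    """Stratified permuted-block randomization with co-randomized pairs.

    Within each stratum, arms are dealt in shuffled blocks containing the
    allocation ratio, so per-stratum arm counts differ by at most one
    partial block.  Members of the same household count as one
    randomization unit: the first member is randomized, later members
    copy its arm.
    """
    ratio = tuple(int(r) for r in ratio)
    if len(ratio) != len(labels):
        raise ConfigError("ratio and labels must have equal length")
    rsum = sum(ratio)
    bsize = rsum if block_size is None else int(block_size)
    if bsize % rsum != 0:
        raise ConfigError(
            f"block_size {bsize} is not a multiple of the ratio sum {rsum}")
    for f in strata_fields:
        if f not in table.columns:
            raise ConfigError(f"stratum field {f!r} missing from table")

    rng = np.random.default_rng(seed)
    out = table.copy()
    out["arm"] = pd.array([None] * len(out), dtype="object")

    # household representatives: first occurrence randomizes the unit
    rep_of: dict = {}
    is_rep = np.ones(len(out), dtype=bool)
    if household_col in out.columns:
        hh = out[household_col]
        seen: dict = {}
        for pos, h in enumerate(hh):
            if pd.isna(h):
                continue
            if h in seen:
                is_rep[pos] = False
                rep_of[pos] = seen[h]
            else:
                seen[h] = pos

    reps = out.index[is_rep]
    strata_key = (out.loc[reps, list(strata_fields)].astype(str)
                  .agg("|".join, axis=1)
                  if strata_fields else pd.Series("all", index=reps))
    block_template = np.repeat(np.arange(len(labels)),
                               np.array(ratio) * (bsize // rsum))
    arm_codes = np.empty(len(out), dtype=int)
    for _, idx in strata_key.groupby(strata_key).groups.items():
        n_units = len(idx)
        n_blocks = -(-n_units // bsize)
        seq = np.concatenate([rng.permutation(block_template)
                              for _ in range(n_blocks)])[:n_units]
        arm_codes[out.index.get_indexer(idx)] = seq
    for pos in range(len(out)):
        if not is_rep[pos]:
            arm_codes[pos] = arm_codes[rep_of[pos]]
    out["arm"] = np.asarray(labels, dtype=object)[arm_codes]
    return out


def generate_cohort(config: GeneratorConfig = GeneratorConfig(),
                    effects: Sequence[ArmEffectSpec] = DEFAULT_EFFECTS,
                    seed: int = 0) -> pd.DataFrame:
    """Generate a complete (no missingness) synthetic trial table.

    Month-12 outcome = baseline + direct arm effect + b * weight change +
    shared household effect + residual noise; weight change = arm effect
    on the mediator + household effect + noise.  Call
    :func:`apply_missingness` afterwards to blank month-12 cells.
    """
    eff = {e.arm: e for e in effects}
    if len(eff) != len(effects):
        raise ConfigError("arm labels in effects must be unique")
    labels = tuple(eff)
    if len(labels) != len(config.allocation):
        raise ConfigError("one ArmEffectSpec required per allocation arm")
    for e in effects:
        for name in e.effects:
            if name not in config.baselines and name != "weight":
                raise ConfigError(f"effect on unknown outcome {name!r}")

    ss = np.random.SeedSequence(seed)
    s_demo, s_alloc, s_med, s_out = [np.random.default_rng(c)
                                     for c in ss.spawn(4)]
    n = config.total_n

    sex = np.where(s_demo.random(n) < config.prop_women, "woman", "man")
    t2d = (s_demo.random(n) < config.prop_t2d).astype(int)
    age = np.clip(s_demo.normal(64.0, 8.0, n), 30, 75).round(0)
    bmi_m0 = np.clip(s_demo.normal(30.0, 3.5, n), 25, 40)
    height = np.where(sex == "woman",
                      s_demo.normal(1.66, 0.06, n),
                      s_demo.normal(1.79, 0.07, n))
    weight_m0 = bmi_m0 * height**2
    pnpla3 = np.where(s_demo.random(n) < config.prop_pnpla3_cc, "CC", "CG/GG")

    household = np.full(n, np.nan)
    if config.n_household_pairs > 0:
        chosen = s_demo.choice(n, size=2 * config.n_household_pairs,
                               replace=False)
        for k in range(config.n_household_pairs):
            household[chosen[2 * k]] = k + 1
            household[chosen[2 * k + 1]] = k + 1

    df = pd.DataFrame({
        "id": [f"S{i + 1:03d}" for i in range(n)],
        "sex": sex, "t2d": t2d, "age": age, "height": height,
        "bmi_m0": bmi_m0,
        "household_id": pd.array(household, dtype="Int64"),
        "pnpla3": pnpla3,
    })
    df = assign_arms(df, config.strata, config.allocation,
                     config.block_size, labels,
                     seed=int(s_alloc.integers(2**31)))

    # shared household effect (per household, applied to mediator & outcomes)
    def household_effect(rng: np.random.Generator) -> np.ndarray:
        if config.household_sd == 0 or config.n_household_pairs == 0:
            return np.zeros(n)
        per_hh = rng.normal(0.0, config.household_sd,
                            config.n_household_pairs)
        out = np.zeros(n)
        hh = df["household_id"].to_numpy(dtype=float, na_value=np.nan)
        mask = ~np.isnan(hh)
        out[mask] = per_hh[hh[mask].astype(int) - 1]
        return out

    a = np.array([eff[arm].mediator_effect_a for arm in df["arm"]])
    weight_change = a + household_effect(s_med) + s_med.normal(
        0.0, config.mediator_sd, n)
    df["weight_m0"] = weight_m0
    df["weight_m12"] = weight_m0 + weight_change
    df["weight_change"] = weight_change
    df["bmi_m12"] = df["weight_m12"] / height**2
    df["bmi_m6"] = (df["bmi_m0"] + df["bmi_m12"]) / 2 + s_med.normal(
        0.0, 0.3 if config.mediator_sd > 0 else 0.0, n)

    for name, spec in config.baselines.items():
        if spec.family == "lognormal":
            base = spec.loc * np.exp(spec.scale * s_out.standard_normal(n))
        else:
            base = s_out.normal(spec.loc, spec.scale, n)
        direct = np.array([eff[arm].effects.get(name, 0.0)
                           for arm in df["arm"]])
        b = config.mediator_to_outcome_b.get(name, 0.0)
        change = (direct + b * weight_change + household_effect(s_out)
                  + s_out.normal(0.0, config.residual_sd.get(name, 0.0), n))
        # truncation applies to the drawn baseline (so month-12 values
        # track the realised baseline exactly when noise-free); additive
        # changes are truncated at 0 only for the positive-support family
        if name == "liver_fat":
            base = np.clip(base, 0.0, 100.0)
        m12 = base + change
        if spec.family == "lognormal":
            m12 = np.clip(m12, 0.0, None)
            if name == "liver_fat":
                m12 = np.clip(m12, 0.0, 100.0)
        df[f"{name}_m0"] = base
        df[f"{name}_m12"] = m12

    df["nafld_m0"] = (df["liver_fat_m0"] > 5.6).astype(int)
    cols = (["id", "arm", "sex", "t2d", "age", "height", "household_id",
             "pnpla3", "nafld_m0", "bmi_m0", "bmi_m6", "bmi_m12"]
            + [f"{o}_m0" for o in OUTCOME_ORDER if f"{o}_m0" in df]
            + [f"{o}_m12" for o in OUTCOME_ORDER if f"{o}_m12" in df]
            + ["weight_change"])
    return df[cols]


def apply_missingness(table: pd.DataFrame, config: GeneratorConfig,
                      seed: int = 0) -> pd.DataFrame:
    """Blank month-12 cells missing-at-random at the configured rates.

    The blanking probability for each subject is logistic in the z-scored
    baseline BMI and diabetes status (coefficients from
    ``config.mar_dependence``), with the intercept solved numerically so
    the *marginal* rate equals the configured per-variable rate.  Only
    month-12 cells are blanked; baseline covariates stay complete, which
    is what makes the mechanism MAR by construction.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    bmi = out["bmi_m0"].to_numpy(dtype=float)
    z = (bmi - bmi.mean()) / (bmi.std() or 1.0)
    eta = (config.mar_dependence.get("bmi_m0", 0.0) * z
           + config.mar_dependence.get("t2d", 0.0)
           * out["t2d"].to_numpy(dtype=float))

    for name, rate in config.missingness_rates.items():
        col = f"{name}_m12"
        if col not in out.columns or rate == 0:
            continue
        if rate >= 1.0:
            raise ConfigError(f"cannot blank all of {col}")
        alpha = brentq(lambda a: expit(a + eta).mean() - rate, -40, 40)
        p = expit(alpha + eta)
        mask = rng.random(len(out)) < p
        out.loc[mask, col] = np.nan
        if name == "weight":
            out.loc[mask, "weight_change"] = np.nan
    return out


def write_trial_csv(table: pd.DataFrame, path) -> None:
    """Write a trial table as CSV: UTF-8, '.' decimal, blanks for missing."""
    table.to_csv(path, index=False, na_rep="")
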