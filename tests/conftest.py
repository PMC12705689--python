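import numpy as np
import pandas as pd
import pytest

from triarm.synthetic_trial import (ArmEffectSpec, BaselineSpec,
                                    GeneratorConfig, apply_missingness,
                                    generate_cohort)


def gaussian_config(n_per_arm: int = 50, residual_sd: float = 3.0,
                    missing: dict | None = None,
                    n_household_pairs: int = 0) -> GeneratorConfig:
    """A Gaussian liver-fat-only trial config used across tests."""
    return GeneratorConfig(
        n_per_arm=n_per_arm,
        baselines={"liver_fat": BaselineSpec("normal", 8.0, 4.0)},
        residual_sd={"liver_fat": residual_sd},
        mediator_to_outcome_b={},
        missingness_rates=missing or {},
        n_household_pairs=n_household_pairs,
    )


def null_effects() -> tuple[ArmEffectSpec, ...]:
    return (ArmEffectSpec("LCPUFA"), ArmEffectSpec("HND"),
            ArmEffectSpec("UC"))


def planted_effects(lcpufa: float = -1.46, hnd: float = -1.76,
                    uc: float = 0.0) -> tuple[ArmEffectSpec, ...]:
    return (ArmEffectSpec("LCPUFA", effects={"liver_fat": lcpufa}),
            ArmEffectSpec("HND", effects={"liver_fat": hnd}),
            ArmEffectSpec("UC", effects={"liver_fat": uc}))


@pytest.fixture(scope="session")
def default_trial() -> pd.DataFrame:
    """One full default-condition trial, complete (no missingness)."""
    return generate_cohort(seed=11)


@pytest.fixture(scope="session")
def gaussian_trial_missing() -> pd.DataFrame:
    """Gaussian liver-fat trial with planted effects and 14% MAR blanking."""
    cfg = gaussian_config(missing={"liver_fat": 0.14})
    tab = generate_cohort(cfg, planted_effects(), seed=5)
    return apply_missingness(tab, cfg, seed=6)


@pytest.fixture()
def toy_completed() -> pd.DataFrame:
    """A deterministic 12-row completed table for exact-algebra checks."""
    rng = np.random.default_rng(99)
    n = 12
    arm = np.array(["LCPUFA", "HND", "UC"] * 4)
    base = rng.normal(8, 3, n).round(3)
    change = rng.normal(0, 2, n).round(3)
    return pd.DataFrame({
        "id": [f"T{i:02d}" for i in range(n)],
        "arm": arm,
        "sex": np.where(rng.random(n) < 0.5, "woman", "man"),
        "t2d": rng.integers(0, 2, n),
        "liver_fat_m0": base,
        "liver_fat_m12": base + change,
    })
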