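"""Orchestration: CSV I/O, routing, gatekeeping contract, subgroups,
sensitivity variants, report provenance."""

import json

import numpy as np
import pandas as pd
import pytest

from conftest import gaussian_config, null_effects, planted_effects
from triarm import harness
from triarm.errors import ConfigError, ParseError
from triarm.harness import RunConfig, fraction_pct, read_trial_csv, write_report
from triarm.synthetic_trial import (GeneratorConfig, apply_missingness,
                                    generate_cohort, write_trial_csv)


class TestCsvRoundTrip:
    def test_round_trip_identity(self, tmp_path):
        cfg = GeneratorConfig(n_per_arm=15)
        tab = apply_missingness(generate_cohort(cfg, seed=3), cfg, seed=4)
        path = tmp_path / "trial.csv"
        write_trial_csv(tab, path)
        back = read_trial_csv(path)
        assert list(back.columns) == list(tab.columns)
        for col in tab.columns:
            if pd.api.types.is_float_dtype(tab[col]):
                np.testing.assert_allclose(back[col], tab[col], rtol=1e-12)
            else:
                assert back[col].fillna(-1).tolist() == \
                    tab[col].fillna(-1).tolist()

    def test_empty_field_is_missing_not_zero(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,arm,sex,t2d,liver_fat_m0,liver_fat_m12\n"
                     "S1,UC,man,0,8.2,\nS2,HND,woman,1,6.0,5.1\n")
        df = read_trial_csv(p)
        assert pd.isna(df.loc[0, "liver_fat_m12"])
        assert df.loc[1, "liver_fat_m12"] == 5.1

    def test_unknown_arm_label_names_row(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,arm,liver_fat_m0\nS1,UC,8.0\nS2,HDN,6.0\n")
        with pytest.raises(ParseError, match="HDN"):
            read_trial_csv(p)

    def test_non_numeric_cell_names_column(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,arm,liver_fat_m0\nS1,UC,oops\n")
        with pytest.raises(ParseError, match="liver_fat_m0"):
            read_trial_csv(p)


def test_fraction_pct_flow_numbers():
    assert round(fraction_pct(1362, 1445)) == 94
    assert fraction_pct(10, 150) < 7.0


class TestPrimaryAnalysis:
    def test_gaussian_trial_recovers_planted_contrasts(self):
        """Planted liver-fat effects are inside the pooled 95% CIs."""
        cfg = gaussian_config(n_per_arm=50,
                              missing={"liver_fat": 0.14})
        tab = apply_missingness(
            generate_cohort(cfg, planted_effects(), seed=71), cfg, seed=72)
        rc = RunConfig(outcomes=("liver_fat",), m=10, seed=5)
        rep = harness.run_primary_analysis(tab, rc)["liver_fat"]
        assert rep["branch"] == "parametric"
        if rep["gate_status"] == "released":
            planted = {"HND vs UC": -1.76, "LCPUFA vs UC": -1.46,
                       "HND vs LCPUFA": -0.30}
            for c in rep["contrasts"]:
                assert c["ci_low"] - 1e-9 <= planted[c["label"]] \
                    <= c["ci_high"] + 1e-9

    def test_skewed_residuals_route_nonparametric(self):
        """Strongly skewed change noise fires the rank-based branch."""
        rng = np.random.default_rng(6)
        cfg = gaussian_config(n_per_arm=40, residual_sd=0.0)
        tab = generate_cohort(cfg, null_effects(), seed=61)
        tab["liver_fat_m12"] = (tab["liver_fat_m0"]
                                + rng.lognormal(0.0, 1.0, len(tab)))
        rc = RunConfig(outcomes=("liver_fat",), m=5, seed=2)
        rep = harness.run_primary_analysis(tab, rc)["liver_fat"]
        assert rep["branch"] == "nonparametric"
        assert rep["routing"]["gaussian"] is False

    def test_null_trial_emits_no_pairwise_contrasts(self):
        """Under the global null, gatekeeping almost always blocks the
        pairwise stage; when the omnibus does fire, contrasts appear."""
        cfg = gaussian_config(n_per_arm=30)
        tab = generate_cohort(cfg, null_effects(), seed=62)
        rc = RunConfig(outcomes=("liver_fat",), m=5, seed=3)
        rep = harness.run_primary_analysis(tab, rc)["liver_fat"]
        if rep["global_test"]["significant"]:
            assert rep["contrasts"]
        else:
            assert rep["gate_status"] == "gatekept"
            assert rep["contrasts"] == []

    def test_per_protocol_uses_complete_cases(self):
        cfg = gaussian_config(n_per_arm=30, missing={"liver_fat": 0.2})
        tab = apply_missingness(
            generate_cohort(cfg, planted_effects(), seed=63), cfg, seed=64)
        rc = RunConfig(outcomes=("liver_fat",), population="per_protocol",
                       seed=1)
        rep = harness.run_primary_analysis(tab, rc)["liver_fat"]
        n_complete = int(tab["liver_fat_m12"].notna().sum())
        assert rep["n"] == n_complete
        assert rep["n"] < len(tab)

    def test_missing_arm_rejected(self):
        cfg = gaussian_config(n_per_arm=10)
        tab = generate_cohort(cfg, null_effects(), seed=1)
        with pytest.raises(ConfigError):
            harness.run_primary_analysis(tab[tab["arm"] != "UC"],
                                         RunConfig())

    def test_reports_are_reproducible_and_carry_provenance(self, tmp_path):
        cfg = gaussian_config(n_per_arm=20, missing={"liver_fat": 0.1})
        tab = apply_missingness(
            generate_cohort(cfg, planted_effects(), seed=65), cfg, seed=66)
        rc = RunConfig(outcomes=("liver_fat",), m=4, seed=8)
        r1 = harness.run_primary_analysis(tab, rc)
        r2 = harness.run_primary_analysis(tab, rc)
        p1, p2 = tmp_path / "r1.json", tmp_path / "r2.json"
        write_report(r1, p1)
        write_report(r2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        meta = json.loads(p1.read_text())["_meta"]
        assert {"config_hash", "seed", "version"} <= set(meta)


@pytest.fixture(scope="module")
def trial():
    cfg = gaussian_config(n_per_arm=50, missing={"liver_fat": 0.1})
    return apply_missingness(
        generate_cohort(cfg, planted_effects(), seed=81), cfg, seed=82)


class TestSubgroups:
    def test_stratifier_dropped_from_covariates(self, trial):
        rc = RunConfig(outcomes=("liver_fat",), subgroups=("sex",), m=3,
                       seed=4)
        out = harness.run_subgroups(trial, rc)
        for level, rep in out["sex"].items():
            if "status" in rep:
                continue
            assert "sex" not in rep["_meta"]["covariates"]
            assert "baseline" in rep["_meta"]["covariates"]

    def test_tiny_levels_skipped(self, trial):
        small = trial.copy()
        small["rare"] = "no"
        small.loc[small.index[:4], "rare"] = "yes"
        rc = RunConfig(outcomes=("liver_fat",), subgroups=("rare",), m=3,
                       seed=4)
        out = harness.run_subgroups(small, rc)
        assert out["rare"]["yes"]["status"] == "skipped"

    def test_absent_column_noted(self, trial):
        rc = RunConfig(outcomes=("liver_fat",), subgroups=("nonexistent",),
                       m=3, seed=4)
        out = harness.run_subgroups(trial, rc)
        assert out["nonexistent"]["status"] == "skipped"


class TestSensitivity:
    def test_no_household_pairs_variant_equals_primary(self):
        cfg = gaussian_config(n_per_arm=30, n_household_pairs=0,
                              missing={"liver_fat": 0.1})
        tab = apply_missingness(
            generate_cohort(cfg, planted_effects(), seed=91), cfg, seed=92)
        rc = RunConfig(outcomes=("liver_fat",), m=4, seed=6)
        out = harness.run_sensitivity(tab, rc)
        assert out["exclude_household_pairs"]["n_dropped"] == 0
        for deltas in out["exclude_household_pairs"]["deltas"].values():
            for d in deltas.values():
                assert d == 0.0

    def test_pair_exclusion_is_small_perturbation(self):
        cfg = gaussian_config(n_per_arm=50, n_household_pairs=4,
                              missing={"liver_fat": 0.1})
        tab = apply_missingness(
            generate_cohort(cfg, planted_effects(), seed=93), cfg, seed=94)
        rc = RunConfig(outcomes=("liver_fat",), m=4, seed=6)
        out = harness.run_sensitivity(tab, rc)
        assert out["exclude_household_pairs"]["n_dropped"] == 8
        for deltas in out["exclude_household_pairs"]["deltas"].values():
            for d in deltas.values():
                assert abs(d) < 0.5 * 3.0  # < 0.5 outcome SDs

    def test_bmi_variant_logs_predictors(self):
        cfg = gaussian_config(n_per_arm=30, missing={"liver_fat": 0.1})
        tab = apply_missingness(
            generate_cohort(cfg, planted_effects(), seed=95), cfg, seed=96)
        rc = RunConfig(outcomes=("liver_fat",), m=4, seed=6)
        out = harness.run_sensitivity(tab, rc)
        preds = out["bmi_visits_in_imputation"]["imputation_predictors"]
        assert "bmi_m6" in preds and "bmi_m12" in preds


def test_operating_characteristic_determinism():
    r1 = harness.simulate_operating_characteristics("null_fwer", 500, 7)
    r2 = harness.simulate_operating_characteristics("null_fwer", 500, 7)
    assert r1["value"] == r2["value"]
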