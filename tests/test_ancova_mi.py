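"""ANCOVA fits, Rubin pooling, omnibus combination, gatekeeping, routing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import gaussian_config, null_effects, planted_effects
from triarm.ancova_mi import (AnalysisSpec, fit_ancova, gatekeep_pairwise,
                              pool_rubin, pooled_global_test,
                              residual_normality)
from triarm.errors import ConfigError
from triarm.mice_pmm import ImputationModel, ImputedStack
from triarm.synthetic_trial import _noise_free, generate_cohort


def _stack(tables, m=None):
    tables = list(tables)
    return ImputedStack(tables=tables, model=ImputationModel(m=max(len(tables), 2)),
                        targets=(), seed=0)


SPEC = AnalysisSpec(outcome="liver_fat")


class TestFitAncova:
    def test_noise_free_contrasts_exact(self):
        cfg = _noise_free(gaussian_config(n_per_arm=20))
        tab = generate_cohort(cfg, planted_effects(lcpufa=-1.46,
                                                   hnd=-1.76), seed=2)
        fit = fit_ancova(tab, SPEC)
        est, _ = fit.contrast("HND", "UC")
        assert est == pytest.approx(-1.76, abs=1e-9)
        est, _ = fit.contrast("LCPUFA", "UC")
        assert est == pytest.approx(-1.46, abs=1e-9)

    def test_matches_normal_equations_oracle(self, toy_completed):
        """Coefficients agree with a direct normal-equations solve."""
        fit = fit_ancova(toy_completed, SPEC)
        X, names, _ = SPEC.design(toy_completed)
        y = SPEC.change(toy_completed).to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_centering_covariates_leaves_contrasts_unchanged(
            self, toy_completed):
        fit1 = fit_ancova(toy_completed, SPEC)
        centered = toy_completed.copy()
        shift = centered["liver_fat_m0"].mean()
        centered["liver_fat_m0"] -= shift
        centered["liver_fat_m12"] -= shift
        fit2 = fit_ancova(centered, SPEC)
        for pair in (("HND", "UC"), ("LCPUFA", "UC"), ("LCPUFA", "HND")):
            assert fit1.contrast(*pair)[0] == pytest.approx(
                fit2.contrast(*pair)[0], abs=1e-10)

    def test_emm_transitivity_within_full_fit(self, toy_completed):
        fit = fit_ancova(toy_completed, SPEC)
        lc_uc = fit.contrast("LCPUFA", "UC")[0]
        hnd_uc = fit.contrast("HND", "UC")[0]
        lc_hnd = fit.contrast("LCPUFA", "HND")[0]
        assert lc_uc - hnd_uc == pytest.approx(lc_hnd, abs=1e-8)

    def test_aliased_column_named(self, toy_completed):
        bad = toy_completed.copy()
        bad["t2d"] = 1  # constant, aliased with the intercept
        with pytest.raises(ConfigError, match="t2d"):
            fit_ancova(bad, SPEC)

    def test_missing_cells_rejected(self, toy_completed):
        bad = toy_completed.copy()
        bad.loc[0, "liver_fat_m12"] = np.nan
        with pytest.raises(ConfigError):
            fit_ancova(bad, SPEC)


class TestPoolRubin:
    def test_hand_computed_fixture(self):
        """estimates {1,3}, variances {1,1}: qbar 2, W 1, B 2, T 4, SE 2."""
        pc = pool_rubin([1.0, 3.0], [1.0, 1.0])
        assert pc.qbar == 2.0
        assert pc.w_within == 1.0
        assert pc.b_between == 2.0
        assert pc.t_total == 4.0
        assert np.sqrt(pc.t_total) == 2.0

    def test_identical_estimates_collapse(self):
        pc = pool_rubin([1.5] * 5, [0.3] * 5)
        assert pc.b_between == 0.0
        assert pc.t_total == pc.w_within

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=10),
           st.floats(0.5, 5))
    def test_homogeneity_and_rubin_identity(self, ests, c):
        var = [1.0] * len(ests)
        base = pool_rubin(ests, var)
        scaled = pool_rubin([c * e for e in ests],
                            [c**2 * v for v in var])
        assert scaled.qbar == pytest.approx(c * base.qbar, rel=1e-9,
                                            abs=1e-9)
        assert scaled.t_total == pytest.approx(c**2 * base.t_total,
                                               rel=1e-9, abs=1e-9)
        m = len(ests)
        assert base.t_total == pytest.approx(
            base.w_within + (1 + 1 / m) * base.b_between, rel=1e-12)
        assert base.ci_low <= base.qbar <= base.ci_high

    def test_m_below_two_rejected(self):
        with pytest.raises(ConfigError):
            pool_rubin([1.0], [1.0])


class TestPooledGlobalTest:
    def test_identical_completions_equal_single_dataset_f(self, toy_completed):
        single = fit_ancova(toy_completed, SPEC)
        f_single, _, _, _ = single.global_f()
        stack = _stack([toy_completed.copy() for _ in range(5)])
        gt = pooled_global_test(stack, SPEC)
        assert gt.statistic == pytest.approx(f_single, abs=1e-8)

    def test_size_under_global_null(self):
        """Rejection rate of the pooled omnibus test sits near nominal."""
        cfg = gaussian_config(n_per_arm=25)
        hits = 0
        n_trials = 400
        for i in range(n_trials):
            tab = generate_cohort(cfg, null_effects(), seed=1000 + i)
            stack = _stack([tab] * 2)
            gt = pooled_global_test(stack, SPEC)
            hits += gt.significant
        rate = hits / n_trials
        assert 0.02 <= rate <= 0.08  # 3-SE band around 0.05 at 400 trials

    def test_power_at_planted_effect(self):
        """A 2-SD planted difference is detected almost always at n=50."""
        cfg = gaussian_config(n_per_arm=50, residual_sd=3.0)
        hits = 0
        for i in range(50):
            tab = generate_cohort(
                cfg, planted_effects(lcpufa=0.0, hnd=-6.0), seed=2000 + i)
            stack = _stack([tab] * 2)
            hits += pooled_global_test(stack, SPEC).significant
        assert hits / 50 > 0.9

    def test_two_arms_rejected(self, toy_completed):
        two = toy_completed[toy_completed["arm"] != "LCPUFA"]
        with pytest.raises(ConfigError):
            pooled_global_test(_stack([two] * 2), SPEC)


class TestGatekeeping:
    def test_nonsignificant_global_emits_no_contrasts(self, toy_completed):
        stack = _stack([toy_completed] * 3)
        gt = pooled_global_test(stack, SPEC)
        gated = gatekeep_pairwise(
            gt if gt.p >= 0.05 else
            type(gt)(statistic=gt.statistic, df1=gt.df1, df2=gt.df2,
                     p=0.40, alpha=0.05),
            stack, SPEC)
        assert gated.status == "gatekept"
        assert gated.contrasts == []

    def test_significant_global_releases_three_comparisons(self):
        cfg = gaussian_config(n_per_arm=50, residual_sd=1.0)
        tab = generate_cohort(cfg, planted_effects(lcpufa=-3.0, hnd=-3.0),
                              seed=3)
        stack = _stack([tab] * 2)
        gt = pooled_global_test(stack, SPEC)
        assert gt.significant
        gated = gatekeep_pairwise(gt, stack, SPEC)
        assert gated.status == "released"
        labels = {c.label for c in gated.contrasts}
        assert labels == {"HND vs LCPUFA", "HND vs UC", "LCPUFA vs UC"}

    def test_familywise_error_never_exceeds_omnibus_rate(self):
        """Any-pairwise rejections are a subset of omnibus rejections."""
        cfg = gaussian_config(n_per_arm=25)
        omni = pairwise_any = 0
        for i in range(150):
            tab = generate_cohort(cfg, null_effects(), seed=5000 + i)
            stack = _stack([tab] * 2)
            gt = pooled_global_test(stack, SPEC)
            gated = gatekeep_pairwise(gt, stack, SPEC)
            omni += gt.significant
            pairwise_any += any(c.p < 0.05 for c in gated.contrasts)
        assert pairwise_any <= omni


class TestResidualNormality:
    def _stack_for(self, resid_sampler, seed, n=150):
        rng = np.random.default_rng(seed)
        base = rng.normal(8, 3, n)
        tab = pd.DataFrame({
            "arm": np.tile(["LCPUFA", "HND", "UC"], n // 3),
            "sex": np.where(rng.random(n) < 0.5, "woman", "man"),
            "t2d": rng.integers(0, 2, n),
            "liver_fat_m0": base,
            "liver_fat_m12": base + resid_sampler(rng, n),
        })
        return _stack([tab] * 2)

    def test_gaussian_residuals_detected(self):
        hits = sum(
            residual_normality(
                self._stack_for(lambda r, n: r.normal(0, 3, n), seed=i),
                SPEC).gaussian
            for i in range(100))
        assert hits >= 95

    def test_lognormal_residuals_flagged(self):
        hits = sum(
            not residual_normality(
                self._stack_for(lambda r, n: r.lognormal(0, 1, n), seed=i),
                SPEC).gaussian
            for i in range(100))
        assert hits >= 95

    def test_threshold_is_strict(self):
        stack = self._stack_for(lambda r, n: r.normal(0, 3, n), seed=0)
        nc = residual_normality(stack, SPEC)
        boundary = residual_normality(stack, SPEC, threshold=nc.w_summary)
        assert boundary.gaussian is False
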