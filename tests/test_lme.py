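import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from cardioscore.lme import (
    INTERCEPT,
    ModelSpec,
    StackedDesign,
    backward_stepwise_aic,
    bootstrap_inference,
    cohens_f2,
    compute_r2,
    compute_vif,
    correlation_matrix,
    fit_lmm,
)
from conftest import make_regression_design


class TestModelSpec:
    def test_nested_sets(self):
        s1, s2, s3 = (ModelSpec.for_set(i) for i in (1, 2, 3))
        assert set(s1.fixed_terms) < set(s2.fixed_terms) < set(s3.fixed_terms)
        assert "starting_factor" in s3.fixed_terms

    def test_unknown_set(self):
        with pytest.raises(ValueError):
            ModelSpec.for_set(4)


class TestFitLMM:
    def test_matches_statsmodels_mixedlm(self):
        """Independent oracle: statsmodels MixedLM, ML estimation."""
        design = make_regression_design(np.random.default_rng(0), group_sd=0.2)
        spec = ModelSpec(1, design.terms)
        fit = fit_lmm(design, spec)
        md = sm.MixedLM(design.y(), design.X(), groups=design.groups()).fit(reml=False)
        beta = np.array([fit.beta[INTERCEPT]] + [fit.beta[t] for t in design.terms])
        assert np.allclose(beta, md.fe_params, atol=1e-6)
        assert abs(fit.llf - md.llf) < 1e-6
        assert abs(fit.sigma2 - md.scale) < 1e-6
        assert abs(fit.sigma_u2 - float(np.asarray(md.cov_re)[0, 0])) < 1e-5

    def test_noiseless_exact_recovery(self):
        design = make_regression_design(
            np.random.default_rng(1), group_sd=0.0, noise_sd=0.0,
            beta={"x1": 1.0, "x2": -0.5, "noise": 0.25},
        )
        fit = fit_lmm(design, ModelSpec(1, design.terms))
        assert abs(fit.beta["x1"] - 1.0) < 1e-6
        assert abs(fit.beta["x2"] + 0.5) < 1e-6
        assert abs(fit.beta["noise"] - 0.25) < 1e-6
        assert abs(fit.beta[INTERCEPT] - 0.5) < 1e-6

    def test_pure_group_shifts(self):
        """ANOVA decomposition: with only per-group offsets, fixed slopes
        vanish and the random-intercept variance matches the shift variance."""
        rng = np.random.default_rng(2)
        G, n_g = 30, 50
        shifts = rng.normal(0, 0.5, G)
        groups = np.repeat(np.arange(G), n_g)
        x = rng.normal(size=G * n_g)
        y = shifts[groups] + rng.normal(0, 0.05, G * n_g)
        frame = pd.DataFrame({"performance": groups, "rr_norm": y, "x1": x})
        fit = fit_lmm(StackedDesign(frame, ("x1",)), ModelSpec(1, ("x1",)))
        assert abs(fit.beta["x1"]) < 0.01
        assert abs(fit.sigma_u2 - shifts.var()) < 0.05

    def test_zero_variance_ratio_equals_ols(self):
        design = make_regression_design(np.random.default_rng(3), group_sd=0.0)
        fit = fit_lmm(design, ModelSpec(1, design.terms), lambda_fixed=0.0)
        X, y = design.X(), design.y()
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        beta = np.array([fit.beta[INTERCEPT]] + [fit.beta[t] for t in design.terms])
        assert np.allclose(beta, ols, atol=1e-8)
        assert fit.sigma_u2 == 0.0

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(4)
        n = 120
        groups = np.repeat([1, 2, 3], 40)
        x1 = rng.normal(size=n)
        frame = pd.DataFrame(
            {"performance": groups, "rr_norm": rng.normal(size=n),
             "x1": x1, "dup": 2.0 * x1}
        )
        with pytest.raises(ValueError, match="dup|x1"):
            fit_lmm(StackedDesign(frame, ("x1", "dup")), ModelSpec(1, ("x1", "dup")))

    def test_constant_column_rejected(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            {"performance": np.repeat([1, 2], 30), "rr_norm": rng.normal(size=60),
             "x1": rng.normal(size=60), "flat": np.ones(60)}
        )
        with pytest.raises(ValueError, match="flat"):
            fit_lmm(StackedDesign(frame, ("x1", "flat")), ModelSpec(1, ("x1", "flat")))

    def test_needs_two_groups(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame(
            {"performance": np.ones(50, int), "rr_norm": rng.normal(size=50),
             "x1": rng.normal(size=50)}
        )
        with pytest.raises(ValueError):
            fit_lmm(StackedDesign(frame, ("x1",)), ModelSpec(1, ("x1",)))


class TestR2:
    def test_noiseless_r2_is_one(self):
        design = make_regression_design(
            np.random.default_rng(7), group_sd=0.0, noise_sd=0.0
        )
        fit = fit_lmm(design, ModelSpec(1, design.terms))
        assert fit.r2_marginal > 1 - 1e-9

    def test_independent_response_r2_near_zero(self):
        design = make_regression_design(
            np.random.default_rng(8), n_per_group=400,
            beta={"x1": 0.0, "x2": 0.0}, group_sd=0.0,
        )
        fit = fit_lmm(design, ModelSpec(1, design.terms))
        assert fit.r2_marginal < 0.01

    def test_matches_sse_sst_oracle_in_ols_limit(self):
        design = make_regression_design(np.random.default_rng(9), group_sd=0.0)
        spec = ModelSpec(1, design.terms)
        fit = fit_lmm(design, spec, lambda_fixed=0.0)
        X, y = design.X(), design.y()
        beta = np.array([fit.beta[INTERCEPT]] + [fit.beta[t] for t in design.terms])
        sse = np.sum((y - X @ beta) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert abs(fit.r2_marginal - (1 - sse / sst)) < 1e-8
        both = compute_r2(fit, design)
        assert abs(both["marginal"] - fit.r2_marginal) < 1e-12
        assert 0.0 <= both["conditional"] <= 1.0


class TestVIF:
    def test_orthogonal_columns(self):
        n = 400
        frame = pd.DataFrame(
            {"performance": np.repeat([1, 2], n // 2), "rr_norm": np.zeros(n),
             "a": np.tile([1.0, -1.0], n // 2),
             "b": np.concatenate([np.ones(n // 2), -np.ones(n // 2)])}
        )
        vif = compute_vif(StackedDesign(frame, ("a", "b")))
        assert abs(vif["a"] - 1.0) < 1e-10 and abs(vif["b"] - 1.0) < 1e-10

    def test_near_duplicate_large_vif(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=500)
        frame = pd.DataFrame(
            {"performance": np.repeat([1, 2], 250), "rr_norm": np.zeros(500),
             "a": x, "b": x + rng.normal(0, 0.02, 500)}
        )
        vif = compute_vif(StackedDesign(frame, ("a", "b")))
        r2 = np.corrcoef(x, frame["b"])[0, 1] ** 2
        assert vif["a"] > 5 and vif["b"] > 5
        assert np.allclose(vif["b"], 1.0 / (1.0 - r2), rtol=1e-6)

    def test_matches_per_column_ols_oracle(self):
        design = make_regression_design(np.random.default_rng(11))
        vif = compute_vif(design)
        for term in design.terms:
            others = [t for t in design.terms if t != term]
            X = np.column_stack(
                [np.ones(design.n_rows)]
                + [design.frame[o].to_numpy() for o in others]
            )
            yj = design.frame[term].to_numpy()
            bh = np.linalg.lstsq(X, yj, rcond=None)[0]
            r2 = 1 - np.sum((yj - X @ bh) ** 2) / np.sum((yj - yj.mean()) ** 2)
            assert abs(vif[term] - 1.0 / (1.0 - r2)) < 1e-8

    def test_perfect_collinearity_is_inf(self):
        x = np.arange(100.0)
        frame = pd.DataFrame(
            {"performance": np.repeat([1, 2], 50), "rr_norm": np.zeros(100),
             "a": x, "b": 3 * x + 1}
        )
        with pytest.warns(UserWarning):
            vif = compute_vif(StackedDesign(frame, ("a", "b")))
        assert np.isinf(vif["a"])


class TestCohensF2:
    def test_null_orthogonal_term_near_zero(self):
        design = make_regression_design(
            np.random.default_rng(12), n_per_group=500, beta={"x1": 1.0, "noise": 0.0}
        )
        f2 = cohens_f2(design, ModelSpec(1, design.terms), "noise")
        assert abs(f2) < 0.01

    def test_single_predictor_half_r2_gives_one(self):
        rng = np.random.default_rng(13)
        n = 4000
        x = rng.normal(size=n)
        y = x + rng.normal(0, 1.0, n)  # R^2 -> 0.5
        frame = pd.DataFrame(
            {"performance": np.repeat([1, 2], n // 2), "rr_norm": y, "x1": x}
        )
        design = StackedDesign(frame, ("x1",))
        spec = ModelSpec(1, ("x1",))
        fit = fit_lmm(design, spec)
        expected = fit.r2_marginal / (1 - fit.r2_marginal)
        f2 = cohens_f2(design, spec, "x1", fit)
        assert abs(f2 - expected) < 1e-8
        assert abs(f2 - 1.0) < 0.15  # stochastic; R^2 ~ 0.5

    def test_matches_refit_oracle(self):
        design = make_regression_design(np.random.default_rng(14))
        spec = ModelSpec(1, design.terms)
        fit_full = fit_lmm(design, spec)
        for term in design.terms:
            fit_red = fit_lmm(design, spec.without(term))
            oracle = (fit_full.r2_marginal - fit_red.r2_marginal) / (1 - fit_full.r2_marginal)
            assert abs(cohens_f2(design, spec, term, fit_full) - oracle) < 1e-8


class TestStepwise:
    def test_fixed_point_when_all_terms_strong(self):
        design = make_regression_design(
            np.random.default_rng(15), beta={"x1": 1.0, "x2": 0.8}, noise_sd=0.3
        )
        spec = ModelSpec(1, design.terms)
        reduced, fit, dropped = backward_stepwise_aic(design, spec)
        assert dropped == ()
        assert reduced.fixed_terms == spec.fixed_terms

    def test_null_term_usually_removed(self):
        """AIC drops a truly null term when its LRT stat < 2, which happens
        with probability P(chi2_1 < 2) ~ 0.84."""
        removed = 0
        for i in range(60):
            design = make_regression_design(np.random.default_rng(200 + i))
            _, _, dropped = backward_stepwise_aic(design, ModelSpec(1, design.terms))
            removed += "noise" in dropped
        assert removed / 60 > 0.7

    def test_dropped_terms_absent_from_fit(self):
        design = make_regression_design(np.random.default_rng(16))
        reduced, fit, dropped = backward_stepwise_aic(design, ModelSpec(1, design.terms))
        for term in dropped:
            assert term not in fit.beta
            assert term not in reduced.fixed_terms


class TestBootstrap:
    def test_deterministic_given_seed(self):
        design = make_regression_design(np.random.default_rng(17))
        spec = ModelSpec(1, design.terms)
        inf1, _ = bootstrap_inference(design, spec, n_boot=100, seed=5)
        inf2, _ = bootstrap_inference(design, spec, n_boot=100, seed=5)
        for t in inf1:
            assert inf1[t].ci_low == inf2[t].ci_low
            assert inf1[t].ci_high == inf2[t].ci_high
            assert inf1[t].p_value == inf2[t].p_value

    def test_ci_contains_point_estimate(self):
        design = make_regression_design(np.random.default_rng(18))
        inf, _ = bootstrap_inference(design, ModelSpec(1, design.terms), 150, seed=1)
        for t, ti in inf.items():
            assert ti.ci_low <= ti.beta <= ti.ci_high

    def test_large_effect_has_tiny_p(self):
        """A |beta|/SE >> 10 effect must reach p < 0.001 (needs B >= 2000
        for the +1-corrected p to resolve below 1/1000)."""
        design = make_regression_design(
            np.random.default_rng(19), beta={"x1": 2.0, "x2": 1.5}, noise_sd=0.2
        )
        inf, _ = bootstrap_inference(design, ModelSpec(1, design.terms), 2500, seed=2)
        assert inf["x1"].p_value < 0.001
        assert inf["x2"].p_value < 0.001

    def test_null_term_large_p(self):
        design = make_regression_design(np.random.default_rng(20), n_per_group=200)
        inf, _ = bootstrap_inference(design, ModelSpec(1, design.terms), 200, seed=3)
        assert inf["noise"].p_value > 0.05

    def test_minimum_b(self):
        design = make_regression_design(np.random.default_rng(21))
        with pytest.raises(ValueError):
            bootstrap_inference(design, ModelSpec(1, design.terms), n_boot=50)


class TestCorrelationMatrix:
    def test_identical_and_orthogonal(self):
        n = 200
        a = np.tile([1.0, -1.0], n // 2)
        b = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        frame = pd.DataFrame(
            {"performance": np.repeat([1, 2], n // 2), "rr_norm": np.zeros(n),
             "a": a, "a2": a.copy(), "b": b}
        )
        r, p, flagged = correlation_matrix(StackedDesign(frame, ("a", "a2", "b")))
        assert abs(r.loc["a", "a2"] - 1.0) < 1e-12
        assert abs(r.loc["a", "b"]) < 1e-12
        assert ("a", "a2", 1.0) in [(x, y, round(v, 6)) for x, y, v in flagged]

    def test_matches_textbook_formula(self):
        design = make_regression_design(np.random.default_rng(22))
        r, p, _ = correlation_matrix(design)
        x = design.frame["x1"].to_numpy()
        y = design.frame["x2"].to_numpy()
        rxy = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert abs(r.loc["x1", "x2"] - rxy) < 1e-10
        n = x.size
        tstat = rxy * np.sqrt((n - 2) / (1 - rxy**2))
        p_oracle = 2 * stats.t.sf(abs(tstat), n - 2)
        assert abs(p.loc["x1", "x2"] - p_oracle) < 1e-8

    def test_constant_column_nan(self):
        frame = pd.DataFrame(
            {"performance": np.repeat([1, 2], 25), "rr_norm": np.zeros(50),
             "a": np.arange(50.0), "flat": np.ones(50)}
        )
        with pytest.warns(UserWarning):
            r, p, _ = correlation_matrix(StackedDesign(frame, ("a", "flat")))
        assert np.isnan(r.loc["a", "flat"])
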