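"""Effective df, AIC, nested tests, smooth tests and credible bands."""

import copy

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import chi2

from tvcm import (
    BasisSpec,
    NestingError,
    TermSpec,
    VCMSpec,
    build_design,
    effective_df,
    fit_gaussian,
    fit_pirls,
    lrt_nested,
    model_aic,
    posterior_bands,
    select_lambda,
    smooth_term_test,
)
from tvcm.fit import _penalty_dense
from tests.test_fit import gaussian_spec


class TestEffectiveDf:
    def test_zero_lambda_counts_all_columns(self, gaussian_frame):
        d = build_design(gaussian_frame, gaussian_spec())
        fit = fit_gaussian(d, [0.0, 0.0])
        per_term, total = effective_df(fit)
        assert abs(total - d.n_cols) < 1e-6
        assert abs(sum(per_term.values()) - total) < 1e-8

    def test_infinite_smoothing_leaves_penalty_null_space(self, gaussian_frame):
        # single smooth (varying intercept) + constant intercept: order-2
        # penalty after centring leaves one df, so the pair totals 2
        spec = VCMSpec(
            "y", "gaussian", (TermSpec(None, "varying_intercept"),),
            "wave", BasisSpec(8, 3, (1.0, 40.0)), 2,
        )
        fit = fit_gaussian(build_design(gaussian_frame, spec), [1e10])
        assert abs(fit.edf_total - 2.0) < 0.01

    def test_trace_matches_dense_hat_matrix(self, gaussian_frame):
        d = build_design(gaussian_frame, gaussian_spec())
        lam = [5.0, 0.3]
        fit = fit_gaussian(d, lam)
        X = d.X.toarray()
        A = X.T @ X + _penalty_dense(d, np.asarray(lam), d.n_cols)
        H = X @ np.linalg.solve(A, X.T)  # dense influence matrix oracle
        assert abs(np.trace(H) - fit.edf_total) < 1e-8


class TestModelAic:
    def test_intercept_only_closed_form(self):
        frame = pd.DataFrame({
            "wave": np.tile(np.arange(1.0, 11.0), 10),
            "smoker": np.r_[np.ones(30), np.zeros(70)],
        })
        spec = VCMSpec("smoker", "binomial", (), "wave", BasisSpec(6, 3, (1, 10)))
        fit = fit_pirls(build_design(frame, spec))
        expected = -2 * (30 * np.log(0.3) + 70 * np.log(0.7)) + 2
        assert abs(model_aic(fit) - expected) < 1e-8

    def test_agrees_with_reference_glm(self, bench_data, bench_spec):
        fit = fit_pirls(build_design(bench_data, bench_spec))
        X = fit.design.X.toarray()
        ref = sm.GLM(fit.design.y, X, family=sm.families.Binomial()).fit()
        assert abs(model_aic(fit) - ref.aic) < 1e-6 * ref.aic

    def test_aic_difference_identity_for_nested_fits(self, bench_data,
                                                     bench_spec):
        f0 = fit_pirls(build_design(bench_data, bench_spec))
        d1 = build_design(bench_data, bench_spec.with_varying("sex"))
        f1 = fit_pirls(d1, [10.0, 10.0])
        lhs = model_aic(f1) - model_aic(f0)
        rhs = (f1.deviance - f0.deviance) + 2 * (f1.edf_total - f0.edf_total)
        assert abs(lhs - rhs) < 1e-10 * max(abs(lhs), 1.0)


class TestLrtNested:
    def test_identical_models_give_p_one(self, bench_data, bench_spec):
        f = fit_pirls(build_design(bench_data, bench_spec))
        res = lrt_nested(f, f)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi_square_reference_value(self):
        # 3.84 on 1 df sits at the 5% point of the chi-square law
        assert abs(chi2.sf(3.84, 1) - 0.050) < 5e-4

    def test_non_nested_rejected(self, bench_data, bench_spec):
        sub = tuple(t for t in bench_spec.terms if t.variable != "sex")
        spec_a = VCMSpec("smoker", "binomial", sub, "wave",
                         bench_spec.basis, 2)
        f_a = fit_pirls(build_design(bench_data, spec_a))
        spec_b = bench_spec.with_varying("age3")
        d_b = build_design(
            bench_data.drop(columns=["sex"]).assign(sex=bench_data["sex"]),
            VCMSpec("smoker", "binomial",
                    tuple(t for t in spec_b.terms if t.variable != "income"),
                    "wave", bench_spec.basis, 2),
        )
        f_b = fit_pirls(d_b, [1.0] * len(d_b.blocks))
        with pytest.raises(NestingError):
            lrt_nested(f_b, f_a)

    def test_invariant_to_row_order(self, bench_data, bench_spec, rng):
        perm = rng.permutation(len(bench_data))
        shuffled = bench_data.iloc[perm].reset_index(drop=True)
        lam = [3.0, 3.0, 3.0]
        f0a = fit_pirls(build_design(bench_data, bench_spec))
        f1a = fit_pirls(build_design(bench_data,
                                     bench_spec.with_varying("age3")), lam)
        f0b = fit_pirls(build_design(shuffled, bench_spec))
        f1b = fit_pirls(build_design(shuffled,
                                     bench_spec.with_varying("age3")), lam)
        ra, rb = lrt_nested(f0a, f1a), lrt_nested(f0b, f1b)
        assert abs(ra.statistic - rb.statistic) < 1e-8 * (ra.statistic + 1)
        assert abs(ra.df - rb.df) < 1e-8


class TestSmoothTermTest:
    def test_zero_coefficients_give_p_one(self, gaussian_frame):
        d = build_design(gaussian_frame, gaussian_spec())
        fit = fit_gaussian(d, [1.0, 1.0])
        fit0 = copy.deepcopy(fit)
        fit0.beta[d.blocks[0].sl] = 0.0
        res = smooth_term_test(fit0, d.blocks[0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_strong_trend_detected(self, gaussian_frame):
        d = build_design(gaussian_frame, gaussian_spec())
        _, fit = select_lambda(d)
        res = smooth_term_test(fit, ("group", "b"))
        assert res.p_value < 0.01
        assert "underestimated" in res.note


class TestPosteriorBands:
    def test_analytic_band_is_z_times_se(self, gaussian_frame):
        d = build_design(gaussian_frame, gaussian_spec())
        fit = fit_gaussian(d, [1.0, 1.0])
        band = posterior_bands(fit, ("group", "b"), level=0.95)
        from tvcm.inference import combined_effect_map

        C = combined_effect_map(fit, ("group", "b"), band.t_grid)
        se = np.sqrt(np.einsum("ij,jk,ik->i", C, fit.Vb, C))
        np.testing.assert_allclose(
            band.upper - band.estimate, 1.959964 * se, atol=1e-6
        )

    def test_simulation_band_converges_to_analytic(self, gaussian_frame):
        d = build_design(gaussian_frame, gaussian_spec())
        fit = fit_gaussian(d, [1.0, 1.0])
        ana = posterior_bands(fit, ("group", "b"))
        sim = posterior_bands(fit, ("group", "b"), method="simulation",
                              n_draws=100_000, seed=9)
        se = (ana.upper - ana.estimate) / 1.959964
        assert np.abs(sim.upper - ana.upper).max() < 0.02 * se.max()
        assert np.abs(sim.lower - ana.lower).max() < 0.02 * se.max()

    def test_pointwise_coverage_of_true_curve(self):
        # Gaussian VCM with a known smooth effect; bands from GCV-selected
        # fits should cover the truth close to nominally on average
        rng = np.random.default_rng(2024)
        n_waves, per, reps = 30, 20, 200
        wave = np.repeat(np.arange(1.0, n_waves + 1), per)
        u = (wave - 1) / (n_waves - 1)
        group = np.tile(np.r_[np.zeros(per // 2), np.ones(per // 2)], n_waves)
        truth = 1.0 + 1.5 * np.sin(2 * np.pi * u)
        spec = VCMSpec(
            "y", "gaussian",
            (TermSpec("g", "varying", "a"),),
            "wave", BasisSpec(8, 3, (1.0, 30.0)), 2,
        )
        hits = []
        for _ in range(reps):
            y = truth * group + rng.normal(0, 1.0, wave.size)
            frame = pd.DataFrame({
                "wave": wave, "g": np.where(group > 0, "b", "a"), "y": y,
            })
            d = build_design(frame, spec)
            _, fit = select_lambda(d)
            band = posterior_bands(fit, ("g", "b"))
            t_true = 1.0 + 1.5 * np.sin(2 * np.pi * (band.t_grid - 1)
                                        / (n_waves - 1))
            hits.append((band.lower <= t_true) & (t_true <= band.upper))
        coverage = np.mean(hits)
        assert 0.90 <= coverage <= 0.98
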