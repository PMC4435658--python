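"""Design assembly and penalized estimation."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize

from tvcm import (
    BasisSpec,
    DegenerateDesignError,
    SchemaError,
    TermSpec,
    VCMSpec,
    binomial_logit,
    build_design,
    fit_gaussian,
    fit_pirls,
    select_lambda,
)
from tvcm.fit import gcv_score
from tvcm.synthetic import Covariate, SmoothEffect, SyntheticConfig, generate

BASIS8 = BasisSpec(8, 3, (1.0, 40.0))


def gaussian_spec(varying=("group",)):
    terms = [TermSpec("group", "varying" if "group" in varying else "constant", "a")]
    return VCMSpec("y", "gaussian", tuple(terms), "wave", BASIS8, 2)


class TestBuildDesign:
    def test_constant_only_binary(self, gaussian_frame):
        spec = gaussian_spec(varying=())
        d = build_design(gaussian_frame, spec)
        assert d.n_const == 2  # intercept + one dummy
        assert d.blocks == []
        assert d.column_index[0] == ("const", "(intercept)", None)
        assert d.column_index[1] == ("const", "group", "b")

    def test_varying_three_levels_gives_three_blocks(self, bench_data, bench_config):
        from tests.conftest import small_spec

        spec = small_spec(bench_config).with_varying("alcohol")
        d = build_design(bench_data, spec)
        alcohol_blocks = [b for b in d.blocks if b.variable == "alcohol"]
        assert len(alcohol_blocks) == 3  # reference level keeps its smooth
        levels = {b.level for b in alcohol_blocks}
        assert "High risk drinker" in levels  # reference included
        dummies = [c for c in d.column_index
                   if c[0] == "const" and c[1] == "alcohol"]
        assert len(dummies) == 2  # non-reference constant dummies only
        # each centred block has n_basis - 1 columns
        k1 = spec.basis.n_basis - 1
        assert all(b.sl.stop - b.sl.start == k1 for b in d.blocks)

    def test_centred_smooth_sums_to_zero_over_waves(self, gaussian_frame):
        d = build_design(gaussian_frame, gaussian_spec())
        fit = fit_gaussian(d, [1.0, 1.0])
        for block in d.blocks:
            vals = fit.smooth_values(block)  # evaluated on the waves
            assert abs(vals.sum()) < 1e-10

    def test_unknown_column_raises(self, gaussian_frame):
        spec = VCMSpec("y", "gaussian", (TermSpec("nope"),), "wave", BASIS8)
        with pytest.raises(SchemaError, match="nope"):
            build_design(gaussian_frame, spec)

    def test_single_level_variable_rejected(self, gaussian_frame):
        frame = gaussian_frame.copy()
        frame["flat"] = "only"
        spec = VCMSpec("y", "gaussian", (TermSpec("flat"),), "wave", BASIS8)
        with pytest.raises(DegenerateDesignError):
            build_design(frame, spec)


class TestGaussianFit:
    def test_zero_penalty_equals_ols(self, gaussian_frame):
        d = build_design(gaussian_frame, gaussian_spec())
        fit = fit_gaussian(d, [0.0, 0.0])
        X = d.X.toarray()
        beta_ols, *_ = np.linalg.lstsq(X, d.y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-8)
        assert abs(fit.edf_total - X.shape[1]) < 1e-6

    def test_huge_lambda_gives_linear_smooths(self, gaussian_frame):
        d = build_design(gaussian_frame, gaussian_spec())
        fit = fit_gaussian(d, [1e8, 1e8])
        waves = d.waves
        for block in d.blocks:
            vals = fit.smooth_values(block)
            coef = np.polyfit(waves, vals, 1)
            resid = vals - np.polyval(coef, waves)
            rng_v = max(vals.max() - vals.min(), 1e-12)
            assert np.abs(resid).max() < 1e-6 * rng_v

    def test_matches_augmented_least_squares_oracle(self, rng):
        # generic-optimizer oracle: stack sqrt(lambda) * Delta Zc rows and
        # solve the whole penalized problem by lstsq (QR path)
        n, lam = 200, (3.7, 0.21)
        wave = rng.integers(1, 41, n).astype(float)
        group = rng.choice(["a", "b"], n)
        y = rng.normal(size=n)
        frame = pd.DataFrame({"wave": wave, "group": group, "y": y})
        d = build_design(frame, gaussian_spec())
        fit = fit_gaussian(d, lam)

        from tvcm.basis import difference_matrix

        X = d.X.toarray()
        rows = [X]
        rhs = [d.y]
        for block, lj in zip(d.blocks, lam):
            D = difference_matrix(8, 2) @ block.Zc
            pad = np.zeros((D.shape[0], X.shape[1]))
            pad[:, block.sl] = np.sqrt(lj) * D
            rows.append(pad)
            rhs.append(np.zeros(D.shape[0]))
        beta_aug, *_ = np.linalg.lstsq(
            np.vstack(rows), np.concatenate(rhs), rcond=None
        )
        np.testing.assert_allclose(fit.beta, beta_aug, atol=1e-8)


def penalized_negloglik(beta, X, y, d, lam):
    # objective matching the penalized-deviance convention:
    # minimize -l(beta) + (1/2) sum_j lambda_j ||Delta gamma_j||^2
    eta = X @ beta
    ll = np.sum(y * eta - np.log1p(np.exp(eta)))
    pen = 0.0
    for block, lj in zip(d.blocks, lam):
        v = beta[block.sl]
        pen += 0.5 * lj * v @ block.S @ v
    return -(ll - pen)


def penalized_negloglik_grad(beta, X, y, d, lam):
    eta = X @ beta
    mu = 1 / (1 + np.exp(-eta))
    g = -(X.T @ (y - mu))
    for block, lj in zip(d.blocks, lam):
        g[block.sl] += lj * block.S @ beta[block.sl]
    return g


class TestPIRLS:
    def test_intercept_only_closed_form(self):
        frame = pd.DataFrame({
            "wave": np.tile(np.arange(1.0, 11.0), 10),
            "smoker": np.r_[np.ones(30), np.zeros(70)],
        })
        spec = VCMSpec("smoker", "binomial", (), "wave", BasisSpec(6, 3, (1, 10)))
        fit = fit_pirls(build_design(frame, spec))
        assert fit.beta.shape == (1,)
        np.testing.assert_allclose(fit.beta[0], np.log(30 / 70), atol=1e-8)

    def test_gaussian_family_reproduces_closed_form(self, gaussian_frame):
        d = build_design(gaussian_frame, gaussian_spec())
        lam = [2.5, 0.4]
        direct = fit_gaussian(d, lam)
        via_pirls = fit_pirls(d, lam)
        np.testing.assert_allclose(via_pirls.beta, direct.beta, atol=1e-10)
        assert via_pirls.deviance == direct.deviance

    def test_matches_numerical_maximizer_and_beats_random(self, rng):
        cfg = SyntheticConfig(
            covariates=[Covariate("g", ("a", "b"), (0.5, 0.5), "a")],
            intercept_log_odds=-0.5,
            constant_log_or={("g", "b"): 0.7},
            varying_log_or={("g", "b"): SmoothEffect("linear", -0.8)},
            n_waves=30, monthly_n=10,
        )
        frame = generate(cfg, seed=5)
        spec = VCMSpec(
            "smoker", "binomial",
            (TermSpec("g", "varying", "a"),), "wave",
            BasisSpec(8, 3, (1.0, 30.0)), 2,
        )
        d = build_design(frame, spec)
        lam = (4.0, 4.0)
        fit = fit_pirls(d, lam)
        X, y = d.X.toarray(), d.y
        f_hat = penalized_negloglik(fit.beta, X, y, d, lam)
        res = scipy.optimize.minimize(
            penalized_negloglik, np.zeros(X.shape[1]),
            args=(X, y, d, lam), jac=penalized_negloglik_grad,
            method="BFGS", options={"gtol": 1e-9, "maxiter": 500},
        )
        assert abs(f_hat - res.fun) < 1e-6 * abs(res.fun)
        for _ in range(50):
            beta_r = fit.beta + rng.normal(0, 0.3, X.shape[1])
            assert penalized_negloglik(beta_r, X, y, d, lam) >= f_hat - 1e-9

    def test_penalized_deviance_monotone_across_iterations(self, bench_data,
                                                           bench_spec):
        d = build_design(bench_data, bench_spec.with_varying("age3"))
        fit = fit_pirls(d, [0.5] * len(d.blocks))
        diffs = np.diff(fit.penalized_deviance_trace)
        assert (diffs <= 1e-8 * (abs(fit.deviance) + 1)).all()

    def test_adding_varying_term_never_increases_deviance_at_zero_lambda(
            self, bench_data, bench_spec):
        f0 = fit_pirls(build_design(bench_data, bench_spec))
        d1 = build_design(bench_data, bench_spec.with_varying("sex"))
        f1 = fit_pirls(d1, [0.0] * len(d1.blocks))
        assert f1.deviance <= f0.deviance + 1e-8


class TestSelectLambda:
    def test_flat_truth_selects_heavy_smoothing(self, null_data, null_config):
        from tests.conftest import small_spec

        spec = small_spec(null_config).with_varying("sex")
        d = build_design(null_data, spec)
        lam, fit = select_lambda(d)
        assert np.log10(lam).max() >= 4.0  # at or near the top of the grid
        # fitted smooths indistinguishable from a flat line
        for block in d.blocks:
            vals = fit.smooth_values(block)
            C = np.zeros((len(d.waves), d.n_cols))
            C[:, block.sl] = d.basis_grid @ block.Zc
            se = np.sqrt(np.einsum("ij,jk,ik->i", C, fit.Vb, C))
            assert (np.abs(vals) <= 2 * se + 1e-8).all()

    def test_wiggly_truth_selects_interior_lambda(self, rng):
        n_waves, per = 40, 40
        wave = np.repeat(np.arange(1.0, n_waves + 1), per)
        u = (wave - 1) / (n_waves - 1)
        y = np.sin(4 * np.pi * u) + rng.normal(0, 0.3, wave.size)
        frame = pd.DataFrame({"wave": wave, "y": y})
        spec = VCMSpec(
            "y", "gaussian", (TermSpec(None, "varying_intercept"),),
            "wave", BasisSpec(15, 3, (1.0, 40.0)), 2,
        )
        lam, fit = select_lambda(build_design(frame, spec))
        assert np.log10(lam).max() < 6.0  # strictly below the grid maximum

    def test_gcv_self_consistent_at_selected_lambda(self, gaussian_frame):
        d = build_design(gaussian_frame, gaussian_spec())
        lam, fit = select_lambda(d, method="gcv")
        refit = fit_gaussian(d, lam)
        assert abs(gcv_score(refit) - gcv_score(fit)) < 1e-10 * gcv_score(fit)

    def test_reml_runs_and_smooths_flat_truth(self, null_data, null_config):
        from tests.conftest import small_spec

        spec = small_spec(null_config).with_varying("sex")
        lam, fit = select_lambda(build_design(null_data, spec), method="reml")
        assert np.isfinite(fit.aic)

    def test_edf_monotone_in_lambda(self, gaussian_frame):
        d = build_design(gaussian_frame, gaussian_spec())
        prev = np.inf
        for lg in [-2, 0, 2, 4, 6]:
            fit = fit_gaussian(d, [10.0**lg] * 2)
            assert fit.edf_total <= prev + 1e-8
            prev = fit.edf_total
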