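"""Model complexity, information criteria, nested tests and credible bands.

Complexity of a penalized fit is measured by effective degrees of freedom
(edf), the trace of the influence matrix at convergence.  Nested models are
compared with a likelihood-ratio test whose reference distribution is a
chi-square with *fractional* degrees of freedom equal to the edf
difference, evaluated through the continuous-df gamma CDF.  Per-smooth
significance uses a Wald statistic on the spline coefficients with rank
equal to the rounded term edf; such p-values are approximate and tend to be
underestimated, so fitted curves should be inspected alongside them.
Uncertainty bands come from the Gaussian posterior N(beta_hat, Vb) of the
coefficients (a Bayesian view of the penalty), either analytically or by
posterior simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
from scipy.stats import chi2, norm

from .basis import bspline_basis
from .exceptions import CovarianceRepairError, DegenerateTestError, NestingError
from .fit import INTERCEPT, FitResult, SmoothBlock, _block_label, _model_aic

logger = logging.getLogger("tvcm")

SMOOTH_P_CAVEAT = (
    "approximate smooth-term p-value; such p-values tend to be "
    "underestimated — inspect the fitted curve as well"
)

__all__ = [
    "TestResult",
    "EffectBand",
    "effective_df",
    "model_aic",
    "lrt_nested",
    "smooth_term_test",
    "posterior_bands",
    "summary_table",
]


@dataclass(frozen=True)
class TestResult:
    """A chi-square test: statistic, (possibly fractional) df, p-value."""

    statistic: float
    df: float
    p_value: float
    null_model_id: str = ""
    alt_model_id: str = ""
    note: str = ""


@dataclass
class EffectBand:
    """Pointwise band for a combined constant + smooth effect over t."""

    t_grid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float


def effective_df(fit: FitResult) -> tuple[dict, float]:
    """Per-term and total effective degrees of freedom.

    Recomputed from the converged weighted crossproduct as the diagonal of
    ``(X'WX + P)^-1 X'WX``; per-term values are the diagonal sums over each
    term's columns (the unpenalized constant columns form one pseudo-term),
    so they add up to the total exactly.
    """
    from .fit import _chol_robust, _edf_parts, _penalty_dense

    design = fit.design
    p = design.n_cols
    A = fit.XtWX + _penalty_dense(design, fit.lam, p)
    A_cho, _ = _chol_robust(A)
    per_term, total, _ = _edf_parts(design, A_cho, fit.XtWX)
    return per_term, total


def model_aic(fit: FitResult) -> float:
    """Conditional AIC: deviance + 2*edf (binomial); -2 loglik + 2(edf+1) Gaussian."""
    return _model_aic(fit.design.spec.family, fit.deviance, fit.loglik, fit.edf_total)


def _labels(fit: FitResult) -> set:
    return {(v, l) for _, v, l in fit.design.column_index}


def lrt_nested(fit_null: FitResult, fit_alt: FitResult) -> TestResult:
    """Likelihood-ratio test of nested penalized fits.

    statistic = deviance_null - deviance_alt (floored at zero); df is the
    effective-df difference; the p-value uses the chi-square law with
    fractional df.  Identical specifications give statistic 0, p = 1.
    """
    if fit_null.n_obs != fit_alt.n_obs:
        raise NestingError("fits use different data (n_obs differ)")
    lab0, lab1 = _labels(fit_null), _labels(fit_alt)
    if lab0 == lab1:
        return TestResult(0.0, 0.0, 1.0,
                          fit_null.model_id(), fit_alt.model_id())
    if not lab0 <= lab1:
        raise NestingError(
            "null model terms are not a subset of the alternative's"
        )
    stat = max(fit_null.deviance - fit_alt.deviance, 0.0)
    df = fit_alt.edf_total - fit_null.edf_total
    if df <= 0:
        raise DegenerateTestError(
            f"non-positive test df ({df:.3f}); the alternative is no more "
            "complex than the null at the selected smoothing"
        )
    p = float(chi2.sf(stat, df))
    return TestResult(stat, float(df), p, fit_null.model_id(), fit_alt.model_id())


def _resolve_block(fit: FitResult, term) -> SmoothBlock:
    if isinstance(term, SmoothBlock):
        return term
    if term is None or term == "s(t)":
        return fit.design.smooth_block(None)
    if isinstance(term, tuple):
        return fit.design.smooth_block(*term)
    raise KeyError(f"cannot resolve smooth term {term!r}")


def smooth_term_test(fit: FitResult, term) -> TestResult:
    """Wald-type test that one smooth deviates from zero.

    Uses gamma' Vb^- gamma with pseudo-inverse rank equal to the rounded
    term edf.  The result carries the usual caveat: these p-values tend to
    be underestimated.
    """
    block = _resolve_block(fit, term)
    delta = fit.beta[block.sl]
    label = _block_label(block)
    edf = fit.edf_per_term.get(label, float(len(delta)))
    rank = int(round(edf))
    if np.allclose(delta, 0.0):
        return TestResult(0.0, max(rank, 1), 1.0, note=SMOOTH_P_CAVEAT,
                          alt_model_id=label)
    if rank < 1:
        rank = 1
    V = fit.Vb[block.sl, block.sl]
    ev, U = sla.eigh(V)
    order = np.argsort(ev)[::-1]
    ev, U = ev[order], U[:, order]
    keep = ev[:rank]
    if keep[-1] <= 0:
        raise DegenerateTestError(f"zero-rank covariance for term {label}")
    proj = U[:, :rank].T @ delta
    stat = float(np.sum(proj**2 / keep))
    p = float(chi2.sf(stat, rank))
    return TestResult(stat, float(rank), p, note=SMOOTH_P_CAVEAT,
                      alt_model_id=label)


def combined_effect_map(fit: FitResult, term, t_grid) -> np.ndarray:
    """Rows map coefficients to the constant + smooth effect at each t."""
    design = fit.design
    block = _resolve_block(fit, term)
    t_grid = np.asarray(t_grid, dtype=float)
    B = bspline_basis(t_grid, design.spec.basis)
    C = np.zeros((t_grid.size, design.n_cols))
    C[:, block.sl] = B @ block.Zc
    if block.variable is None:
        C[:, design.const_col(INTERCEPT, None)] = 1.0
    else:
        try:
            C[:, design.const_col(block.variable, block.level)] = 1.0
        except KeyError:
            pass  # reference level: no constant counterpart, smooth alone
    return C


def posterior_bands(
    fit: FitResult,
    term,
    t_grid=None,
    level: float = 0.95,
    method: str = "analytic",
    n_draws: int = 10000,
    seed: int | None = None,
) -> EffectBand:
    """Pointwise credible band for a combined constant + smooth effect.

    The coefficient posterior is N(beta_hat, Vb); ``analytic`` uses the
    Gaussian quantile, ``simulation`` draws at least 10,000 coefficient
    vectors (seeded) and takes pointwise quantiles.
    """
    design = fit.design
    if t_grid is None:
        t_grid = design.waves
    t_grid = np.asarray(t_grid, dtype=float)
    C = combined_effect_map(fit, term, t_grid)
    est = C @ fit.beta
    Vsub = fit.Vb
    if method == "analytic":
        var = np.einsum("ij,jk,ik->i", C, Vsub, C)
        var = np.clip(var, 0.0, None)
        se = np.sqrt(var)
        z = norm.ppf(0.5 + level / 2.0)
        return EffectBand(t_grid, est, est - z * se, est + z * se, level)
    if method != "simulation":
        raise ValueError(f"unknown band method {method!r}")
    n_draws = max(int(n_draws), 10000)
    rng = np.random.default_rng(seed)
    try:
        L = np.linalg.cholesky(Vsub)
    except np.linalg.LinAlgError:
        ev, U = sla.eigh(Vsub)
        n_neg = int(np.sum(ev < 0))
        floor = 1e-12 * max(ev.max(), 1.0)
        if ev.min() < -1e-6 * max(ev.max(), 1.0):
            raise CovarianceRepairError(
                f"posterior covariance strongly non-PSD ({n_neg} negative "
                "eigenvalues)"
            ) from None
        logger.warning(
            "posterior covariance repaired by clipping %d small/negative "
            "eigenvalues", n_neg,
        )
        L = U @ np.diag(np.sqrt(np.clip(ev, floor, None)))
    draws = fit.beta + (L @ rng.standard_normal((Vsub.shape[0], n_draws))).T
    curves = draws @ C.T
    lo = np.quantile(curves, (1 - level) / 2.0, axis=0)
    hi = np.quantile(curves, 1 - (1 - level) / 2.0, axis=0)
    return EffectBand(t_grid, est, lo, hi, level)


def summary_table(fit: FitResult, level: float = 0.95):
    """Fit summary: one row per constant dummy (OR, CI, p) and per smooth (edf, p)."""
    import pandas as pd

    z = norm.ppf(0.5 + level / 2.0)
    rows = []
    for i, (kind, var, lev) in enumerate(fit.design.column_index):
        if kind != "const" or var == INTERCEPT:
            continue
        b = fit.beta[i]
        se = np.sqrt(max(fit.Vb[i, i], 0.0))
        p = 2.0 * norm.sf(abs(b) / se) if se > 0 else np.nan
        rows.append({
            "variable": var, "level": lev, "term": f"{var}={lev}",
            "or": np.exp(b), "or_lower": np.exp(b - z * se),
            "or_upper": np.exp(b + z * se), "edf": 1.0, "p_value": p,
        })
    for block in fit.design.blocks:
        label = _block_label(block)
        tr = smooth_term_test(fit, block)
        rows.append({
            "variable": block.variable or "(time)", "level": block.level,
            "term": label, "or": np.nan, "or_lower": np.nan,
            "or_upper": np.nan, "edf": fit.edf_per_term.get(label, np.nan),
            "p_value": tr.p_value,
        })
    return pd.DataFrame(rows)
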