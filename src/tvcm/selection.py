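"""Two-stage model building: screening, then forward selection.

Stage one screens every covariate (and the time-varying intercept): each is
allowed time-varying coefficients in turn, with all other effects constant,
and the resulting model is tested against the all-constant logistic model
with a likelihood-ratio test.  Stage two builds the final model by forward
selection among the screened candidates, starting from the most significant
one; at each round the next candidate is the one whose per-level smooths
explain the largest share of the previous model's deviance residuals, and
it enters only if its nested LRT is significant.  The time-varying
intercept is tried last, and only if it passed screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SelectionError, TVCMError
from .fit import (
    FitResult,
    VCMSpec,
    build_design,
    fit_pirls,
    select_lambda,
)
from .inference import lrt_nested

logger = logging.getLogger("tvcm")

__all__ = ["screen_varying", "rank_candidates", "forward_select", "SelectionTrace"]

_INTERCEPT_CAND = "(time)"


#: Lambda-search settings for repeated model-building fits: a coarser
#: 11-point shared-lambda grid plus a lean Nelder-Mead refinement.  The
#: criterion surface is flat near its optimum, so screening p-values are
#: insensitive to the last digit of lambda while whole-pipeline runs stay
#: affordable.
SEARCH_GRID = np.linspace(-4.0, 6.0, 11)
REFINE_EVALS = 25


def _fit_spec(data, spec: VCMSpec, lambda_method: str) -> FitResult:
    design = build_design(data, spec)
    if design.blocks:
        _, fit = select_lambda(design, method=lambda_method,
                               grid=SEARCH_GRID,
                               max_refine_evals=REFINE_EVALS)
        return fit
    return fit_pirls(design)


def screen_varying(
    data: pd.DataFrame,
    base_spec: VCMSpec,
    alpha: float = 0.05,
    lambda_method: str = "gcv",
    include_intercept: bool = True,
) -> pd.DataFrame:
    """Screen every covariate, plus the varying intercept, one at a time.

    Returns one row per candidate with the LRT p-value and AIC of the
    one-varying-term model, sorted by p-value then AIC.  Fit failures are
    recorded in the ``error`` column rather than raised.
    """
    base_fit = fit_pirls(build_design(data, base_spec))
    candidates = [t.variable for t in base_spec.terms if t.variable is not None]
    if include_intercept:
        candidates.append(None)  # the time-varying intercept
    rows = []
    fits = {}
    for var in candidates:
        name = var if var is not None else _INTERCEPT_CAND
        spec = base_spec.with_varying(var)
        try:
            fit = _fit_spec(data, spec, lambda_method)
            fits[name] = fit
            test = lrt_nested(base_fit, fit)
            logger.info("screened %s: p=%.3g aic=%.1f edf=%.2f",
                        spec.describe(), test.p_value, fit.aic,
                        fit.edf_total)
            rows.append({
                "candidate": name, "description": spec.describe(),
                "statistic": test.statistic, "df": test.df,
                "p_value": test.p_value, "aic": fit.aic,
                "edf": fit.edf_total, "significant": test.p_value < alpha,
                "error": "",
            })
        except TVCMError as e:
            logger.warning("screening fit failed for %s: %s", name, e)
            rows.append({
                "candidate": name, "description": spec.describe(),
                "statistic": np.nan, "df": np.nan, "p_value": np.nan,
                "aic": np.nan, "edf": np.nan, "significant": False,
                "error": str(e),
            })
    table = pd.DataFrame(rows, columns=[
        "candidate", "description", "statistic", "df", "p_value", "aic",
        "edf", "significant", "error",
    ])
    table = table.sort_values(
        ["p_value", "aic", "candidate"], na_position="last"
    ).reset_index(drop=True)
    table.attrs["base_aic"] = base_fit.aic
    table.attrs["base_edf"] = base_fit.edf_total
    table.attrs["alpha"] = alpha
    # in-memory reuse by forward_select; absent after a CSV round trip
    table.attrs["fits"] = fits
    table.attrs["base_fit"] = base_fit
    return table


def _deviance_residuals(fit: FitResult) -> np.ndarray:
    design = fit.design
    y = design.y
    eta = design.X @ fit.beta
    if design.spec.family == "binomial":
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        d_i = -2.0 * (y * np.log(mu) + (1 - y) * np.log1p(-mu))
        return np.sign(y - mu) * np.sqrt(np.clip(d_i, 0.0, None))
    return y - eta


def rank_candidates(
    current_fit: FitResult,
    data: pd.DataFrame,
    candidates,
    lambda_method: str = "gcv",
) -> list[tuple[str, float]]:
    """Order candidates by deviance explained in a residual smooth fit.

    For each candidate the deviance residuals of the current fit are
    modelled (Gaussian) on per-level smooths of time alone; the score is
    the proportion of residual deviance explained, 1 - RSS/TSS.  Ties break
    deterministically by candidate name.
    """
    if not candidates:
        return []
    resid = _deviance_residuals(current_fit)
    rdata = data.copy()
    rdata["_resid"] = resid
    base = current_fit.design.spec
    scores = []
    for var in candidates:
        from .fit import TermSpec

        ref = next(
            (t.reference_level for t in base.terms if t.variable == var), None
        )
        terms = (TermSpec(var, "smooth_only", ref),) if var is not None else (
            TermSpec(None, "varying_intercept"),
        )
        spec = VCMSpec(
            response="_resid", family="gaussian", terms=terms,
            modifier=base.modifier, basis=base.basis,
            penalty_order=base.penalty_order,
        )
        design = build_design(rdata, spec)
        _, rfit = select_lambda(design, method=lambda_method,
                                grid=SEARCH_GRID,
                                max_refine_evals=REFINE_EVALS)
        tss = float(np.sum((resid - resid.mean()) ** 2))
        score = max(0.0, 1.0 - rfit.deviance / tss) if tss > 0 else 0.0
        scores.append((var if var is not None else _INTERCEPT_CAND, score))
    scores.sort(key=lambda vs: (-vs[1], str(vs[0])))
    return scores


@dataclass
class SelectionTrace:
    """Forward-selection audit trail: every model tried, in order."""

    steps: list[dict] = field(default_factory=list)

    def add(self, **kw):
        logger.info(
            "model %s (%s): p=%s aic=%.1f edf=%.2f accepted=%s",
            kw.get("model"), kw.get("description"), kw.get("p_value"),
            kw.get("aic", float("nan")), kw.get("edf", float("nan")),
            kw.get("accepted"),
        )
        self.steps.append(kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def forward_select(
    data: pd.DataFrame,
    base_spec: VCMSpec,
    screened: pd.DataFrame,
    alpha: float = 0.05,
    lambda_method: str = "gcv",
) -> tuple[FitResult, SelectionTrace]:
    """Build the final model from the screened candidates.

    Starts from the most significant screened variable; each round ranks
    the remaining screened candidates on the current residuals and tests
    the candidates in rank order, adding the first whose nested LRT has
    p < alpha; a round with no acceptance stops the search.  The
    time-varying intercept is tested last (if
    screened significant).  Returns the final fit and the full trace; when
    nothing screens significant the all-constant logistic model is
    returned unchanged.  Screening fits are reused when available.
    """
    trace = SelectionTrace()
    sig = screened[(screened["significant"]) & (screened["error"] == "")]
    sig_vars = [c for c in sig["candidate"] if c != _INTERCEPT_CAND]
    intercept_screened = _INTERCEPT_CAND in set(sig["candidate"])

    base_fit = screened.attrs.get("base_fit")
    if base_fit is None:
        base_fit = fit_pirls(build_design(data, base_spec))
    trace.add(model="LM", description=base_spec.describe(), p_value=np.nan,
              null_model="", aic=base_fit.aic, edf=base_fit.edf_total,
              added=None, accepted=True)
    if not sig_vars and not intercept_screened:
        return base_fit, trace

    current_fit = base_fit
    current_spec = base_spec
    current_id = "LM"
    included: list[str] = []
    step = 0

    if sig_vars:
        first = sig_vars[0]
        spec1 = base_spec.with_varying(first)
        try:
            fit1 = screened.attrs.get("fits", {}).get(first)
            if fit1 is None:
                fit1 = _fit_spec(data, spec1, lambda_method)
        except TVCMError as e:
            raise SelectionError(
                f"fit of the first selected term ({first}) failed: {e}"
            ) from e
        test1 = lrt_nested(base_fit, fit1)
        step += 1
        mid = f"M{step}"
        trace.add(model=mid, description=spec1.describe(),
                  p_value=test1.p_value, null_model=current_id,
                  aic=fit1.aic, edf=fit1.edf_total, added=first,
                  accepted=True)
        current_fit, current_spec, current_id = fit1, spec1, mid
        included.append(first)

        remaining = [v for v in sig_vars if v not in included]
        while remaining:
            ranked = rank_candidates(
                current_fit, data, remaining, lambda_method
            )
            accepted_any = False
            for cand, score in ranked:
                spec_c = current_spec.with_varying(cand)
                try:
                    fit_c = _fit_spec(data, spec_c, lambda_method)
                    test_c = lrt_nested(current_fit, fit_c)
                except TVCMError as e:
                    logger.warning("candidate fit failed for %s: %s", cand, e)
                    remaining.remove(cand)
                    continue
                step += 1
                accepted = test_c.p_value < alpha
                trace.add(model=f"M{step}", description=spec_c.describe(),
                          p_value=test_c.p_value, null_model=current_id,
                          aic=fit_c.aic, edf=fit_c.edf_total, added=cand,
                          accepted=accepted, rank_score=score)
                remaining.remove(cand)
                if accepted:
                    current_fit, current_spec = fit_c, spec_c
                    current_id = f"M{step}"
                    included.append(cand)
                    accepted_any = True
                    break
            if not accepted_any:
                break

    if intercept_screened:
        spec_t = current_spec.with_varying(None)
        try:
            fit_t = _fit_spec(data, spec_t, lambda_method)
            test_t = lrt_nested(current_fit, fit_t)
            step += 1
            accepted = test_t.p_value < alpha
            trace.add(model=f"M{step}", description=spec_t.describe(),
                      p_value=test_t.p_value, null_model=current_id,
                      aic=fit_t.aic, edf=fit_t.edf_total, added=_INTERCEPT_CAND,
                      accepted=accepted)
            if accepted:
                current_fit, current_spec = fit_t, spec_t
                current_id = f"M{step}"
        except TVCMError as e:
            logger.warning("varying-intercept fit failed: %s", e)

    return current_fit, trace
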