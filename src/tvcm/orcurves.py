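"""Odds-ratio-over-time curves for non-reference categories.

For a category with constant coefficient b and centred smooth a(t), the
curve is OR(t) = exp(b + a(t)); the band exponentiates the posterior band
of the combined effect.  Reference categories have no odds ratio (they are
the baseline), so requesting one is refused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import TVCMError
from .fit import FitResult
from .inference import posterior_bands

__all__ = ["ORCurve", "ReferenceLevelError", "or_curve"]


class ReferenceLevelError(TVCMError):
    """Odds ratio plots cannot be produced for the reference categories."""


@dataclass
class ORCurve:
    """Pointwise odds-ratio curve with its credible band."""

    variable: str
    level: str
    t_grid: np.ndarray
    or_point: np.ndarray
    or_lower: np.ndarray
    or_upper: np.ndarray
    ci_level: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t_grid, "or": self.or_point,
            "lower": self.or_lower, "upper": self.or_upper,
        })


def or_curve(
    fit: FitResult,
    variable: str,
    level: str,
    t_grid=None,
    ci_level: float = 0.95,
    band_method: str = "analytic",
    seed: int | None = None,
) -> ORCurve:
    """Odds-ratio curve exp(b_level + a_level(t)) with credible band.

    ``t_grid`` defaults to the observed waves; pass a finer grid for smooth
    plots.  The band is the exponentiated posterior band of the combined
    constant + smooth effect, so pointwise ordering is preserved.
    """
    design = fit.design
    block = design.smooth_block(variable, level)
    try:
        design.const_col(variable, level)
    except KeyError:
        raise ReferenceLevelError(
            f"odds ratio plots cannot be produced for the reference "
            f"categories ({variable!r}={level!r})"
        ) from None
    band = posterior_bands(
        fit, block, t_grid=t_grid, level=ci_level,
        method=band_method, seed=seed,
    )
    return ORCurve(
        variable=variable, level=level, t_grid=band.t_grid,
        or_point=np.exp(band.estimate), or_lower=np.exp(band.lower),
        or_upper=np.exp(band.upper), ci_level=ci_level,
    )
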