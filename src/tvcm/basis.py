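"""B-spline bases and difference penalties for P-spline smoothing.

A P-spline represents a smooth coefficient function a(t) as a linear
combination of ``n_basis`` B-spline functions on an equally spaced knot
grid, with a difference penalty of order ``d`` on adjacent spline
coefficients controlling the roughness.  The penalty's null space contains
the polynomials of degree ``d - 1``, so heavy penalization shrinks the
smooth toward such a polynomial (a straight line for the default d = 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .exceptions import InvalidPenaltyError, OutOfDomainError

__all__ = ["BasisSpec", "PenaltySpec", "difference_matrix", "bspline_basis"]


@dataclass(frozen=True)
class BasisSpec:
    """Dimension, degree and domain of a B-spline basis.

    Parameters
    ----------
    n_basis : int
        Number of basis functions (columns of the design block).
    degree : int
        Polynomial degree of the B-splines; 3 (cubic) is the usual choice.
    domain : tuple of float
        Closed interval ``[t_min, t_max]`` of the effect modifier.
    """

    n_basis: int
    degree: int
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_basis <= self.degree:
            raise ValueError(
                f"n_basis ({self.n_basis}) must exceed degree ({self.degree})"
            )
        if self.degree < 0:
            raise ValueError("degree must be nonnegative")
        lo, hi = self.domain
        if not np.isfinite([lo, hi]).all() or hi <= lo:
            raise ValueError(f"degenerate domain {self.domain!r}")

    @property
    def knots(self) -> np.ndarray:
        """Full knot vector: equally spaced, extended by `degree` knots per side.

        With ``m = n_basis - degree`` interior intervals on the domain the
        vector has ``m + 2*degree + 1`` entries and defines exactly
        ``n_basis`` B-spline functions.
        """
        lo, hi = self.domain
        m = self.n_basis - self.degree
        h = (hi - lo) / m
        return lo + h * np.arange(-self.degree, m + self.degree + 1)


@dataclass(frozen=True)
class PenaltySpec:
    """Difference order and smoothing parameter of a P-spline penalty."""

    order: int
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise InvalidPenaltyError(f"penalty order must be >= 1, got {self.order}")
        if self.lam < 0:
            raise ValueError(f"smoothing parameter must be nonnegative, got {self.lam}")


def difference_matrix(n_basis: int, order: int) -> np.ndarray:
    """Finite-difference matrix of shape ``(n_basis - order, n_basis)``.

    Row ``i`` applies the order-``d`` difference to coefficients
    ``i .. i + d``.  Its null space is exactly the polynomials of degree
    ``< order`` evaluated on the coefficient indices.
    """
    if not 1 <= order < n_basis:
        raise InvalidPenaltyError(
            f"difference order must satisfy 1 <= order < n_basis; "
            f"got order={order}, n_basis={n_basis}"
        )
    return np.diff(np.eye(n_basis), n=order, axis=0)


def penalty_matrix(n_basis: int, order: int) -> np.ndarray:
    """Penalty matrix ``D'D`` for the order-``d`` difference penalty."""
    D = difference_matrix(n_basis, order)
    return D.T @ D


def bspline_basis(t_values, spec: BasisSpec, sparse: bool = False):
    """Evaluate the B-spline basis at ``t_values``.

    Returns an ``(n, n_basis)`` design matrix whose rows sum to one
    (partition of unity); column ``l`` is the l-th basis function,
    ordered left to right by support.  The right domain boundary is a
    valid input (the last knot interval is treated as closed).

    Parameters
    ----------
    t_values : array-like
        Modifier values; every value must lie in ``spec.domain``.
    spec : BasisSpec
    sparse : bool
        If True return a ``scipy.sparse.csr_array`` (each row has at most
        ``degree + 1`` structural nonzeros); otherwise a dense ndarray.
    """
    t = np.asarray(t_values, dtype=float)
    if t.ndim != 1:
        t = np.atleast_1d(t.ravel())
    lo, hi = spec.domain
    bad = (t < lo) | (t > hi) | ~np.isfinite(t)
    if bad.any():
        offender = t[bad][0]
        raise OutOfDomainError(
            f"modifier value {offender!r} outside basis domain [{lo}, {hi}]"
        )
    B = BSpline.design_matrix(t, spec.knots, spec.degree, extrapolate=False)
    if sparse:
        return B.tocsr()
    return B.toarray()
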