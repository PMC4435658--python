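"""Design assembly and penalized estimation of varying coefficient models.

A varying coefficient model (VCM) relates a response to categorical
covariates whose effects may drift smoothly with an effect modifier t
(calendar time here):

    g(mu_i) = b0 + sum_j b_j Z_ij + a_0(t_i) + sum_j X_ij a_j(t_i)

Constant effects ``b_j`` sit in an ordinary dummy-coded block ``Z``; every
time-varying effect ``a_j(t)`` is a P-spline, entering the design through
``R_j = D_j B_j`` where ``D_j`` is the diagonal of the term's indicator and
``B_j`` the B-spline basis evaluated at t.  Each smooth is centred to sum
to zero over the observed waves so that its constant counterpart stays
identifiable.  Estimation is penalized least squares (Gaussian) or
penalized iteratively reweighted least squares / Fisher scoring (logistic),
with per-smooth smoothing parameters chosen by GCV or a Laplace-approximate
REML criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.optimize import minimize

from .basis import BasisSpec, PenaltySpec, bspline_basis, penalty_matrix
from .exceptions import (
    ConvergenceError,
    DegenerateDesignError,
    RankDeficiencyError,
    SchemaError,
    SelectionError,
)

logger = logging.getLogger("tvcm")

#: default PIRLS controls (standard GLM smoothing choices)
PIRLS_TOL = 1e-8
PIRLS_MAXIT = 100
QUASI_SEP_ETA = 30.0
QUASI_SEP_FRAC = 0.01
CONST_RIDGE = 1e-8

#: default smoothing-parameter search: 21-point log10 grid on [1e-4, 1e6]
LAMBDA_GRID = np.linspace(-4.0, 6.0, 21)
LOGLAM_BOUNDS = (-6.0, 8.0)

INTERCEPT = "(intercept)"
TIME_SMOOTH = "(time)"

__all__ = [
    "TermSpec",
    "VCMSpec",
    "Family",
    "DesignBlocks",
    "FitResult",
    "gaussian_family",
    "binomial_logit",
    "build_design",
    "fit_gaussian",
    "fit_pirls",
    "select_lambda",
]


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermSpec:
    """One model term.

    role ``constant``: dummy-coded fixed effect only.
    role ``varying``: dummies for non-reference levels *plus* one centred
    smooth per level (reference included) — a varying term always keeps its
    constant counterpart.
    role ``varying_intercept``: a single centred smooth of t, no variable.
    role ``smooth_only``: per-level smooths without the constant dummies
    (used internally when ranking candidates on residuals).
    """

    variable: str | None
    role: str = "constant"
    reference_level: str | None = None

    def __post_init__(self):
        if self.role not in {"constant", "varying", "varying_intercept", "smooth_only"}:
            raise ValueError(f"unknown term role {self.role!r}")
        if self.role == "varying_intercept" and self.variable is not None:
            raise ValueError("varying_intercept terms carry no variable")
        if self.role != "varying_intercept" and self.variable is None:
            raise ValueError("variable terms need a variable name")


@dataclass(frozen=True)
class VCMSpec:
    """Full model specification: response, family, terms, modifier, basis."""

    response: str
    family: str  # "gaussian" | "binomial"
    terms: tuple[TermSpec, ...]
    modifier: str
    basis: BasisSpec
    penalty_order: int = 2

    def __post_init__(self):
        if self.family not in {"gaussian", "binomial"}:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "terms", tuple(self.terms))
        n_vi = sum(t.role == "varying_intercept" for t in self.terms)
        if n_vi > 1:
            raise ValueError("at most one varying intercept")

    def describe(self) -> str:
        bits = []
        for t in self.terms:
            if t.role == "varying_intercept":
                bits.append("s(t)")
            elif t.role in {"varying", "smooth_only"}:
                bits.append(f"s(t):{t.variable}")
        return "LM" if not bits else "LM + " + " + ".join(bits)

    def with_varying(self, variable: str | None) -> "VCMSpec":
        """Copy of the spec with one term switched to time-varying.

        ``variable=None`` adds the time-varying intercept.
        """
        if variable is None:
            if any(t.role == "varying_intercept" for t in self.terms):
                return self
            return replace(self, terms=self.terms + (TermSpec(None, "varying_intercept"),))
        terms = tuple(
            replace(t, role="varying") if t.variable == variable else t
            for t in self.terms
        )
        if terms == self.terms and not any(t.variable == variable for t in terms):
            raise ValueError(f"variable {variable!r} not in spec")
        return replace(self, terms=terms)


@dataclass(frozen=True)
class Family:
    """Exponential-family ingredients: link, inverse link, variance."""

    name: str
    link: callable
    linkinv: callable
    variance: callable
    scale_fixed: float | None  # None -> estimated (Gaussian)

    def deviance(self, y, mu):
        if self.name == "binomial":
            # 0/1 responses: saturated log-likelihood is zero
            with np.errstate(divide="ignore", invalid="ignore"):
                d = y * np.log(mu) + (1 - y) * np.log1p(-mu)
            return -2.0 * np.sum(d)
        return float(np.sum((y - mu) ** 2))


def gaussian_family() -> Family:
    return Family("gaussian", lambda m: m, lambda e: e, lambda m: np.ones_like(m), None)


def binomial_logit() -> Family:
    def linkinv(eta):
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))

    return Family(
        "binomial",
        lambda m: np.log(m / (1.0 - m)),
        linkinv,
        lambda m: m * (1.0 - m),
        1.0,
    )


def get_family(name: str) -> Family:
    return {"gaussian": gaussian_family, "binomial": binomial_logit}[name]()


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

@dataclass
class SmoothBlock:
    """One centred P-spline block R_j = D_j B_j Z_c."""

    variable: str | None      # None for the varying intercept
    level: str | None
    sl: slice                 # columns of this block in the full design
    Zc: np.ndarray            # (k, k-1) centring transform, gamma = Zc @ delta
    S: np.ndarray             # (k-1, k-1) transformed difference penalty


@dataclass
class DesignBlocks:
    """Assembled design: constant block Z, smooth blocks, bookkeeping."""

    X: sp.csr_array           # n x p full design [Z | R_1 | ... | R_q]
    y: np.ndarray
    n_const: int
    blocks: list[SmoothBlock]
    column_index: list[tuple]  # per column: ("const"|"smooth", variable, level)
    spec: VCMSpec
    t: np.ndarray
    waves: np.ndarray          # unique observed modifier values
    basis_grid: np.ndarray     # B evaluated at waves (dense, small)

    _row_counts: np.ndarray = None
    _XtX: np.ndarray = None
    _Xty: np.ndarray = None

    def weighted_crossprod(self, w=None, target=None):
        """(X'WX, X'W t) with CSR row scaling; the unweighted pair is cached."""
        X = self.X
        t = self.y if target is None else target
        if w is None:
            if self._XtX is None:
                self._XtX = (X.T @ X).toarray()
                self._Xty = X.T @ self.y
            if target is None:
                return self._XtX, self._Xty
            return self._XtX, X.T @ t
        if self._row_counts is None:
            self._row_counts = np.diff(X.indptr)
        sw = np.sqrt(w)
        Xw = X.copy()
        Xw.data = X.data * np.repeat(sw, self._row_counts)
        XtWX = (Xw.T @ Xw).toarray()
        XtWt = Xw.T @ (sw * t)
        return XtWX, XtWt

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    def const_col(self, variable, level) -> int:
        key = ("const", variable, level)
        try:
            return self.column_index.index(key)
        except ValueError:
            raise KeyError(f"no constant column for {variable!r}={level!r}") from None

    def smooth_block(self, variable, level=None) -> SmoothBlock:
        for b in self.blocks:
            if b.variable == variable and (level is None or b.level == level):
                return b
        raise KeyError(f"no smooth block for {variable!r} level {level!r}")


def _levels_of(data: pd.DataFrame, variable: str) -> list:
    col = data[variable]
    if isinstance(col.dtype, pd.CategoricalDtype):
        cats = [c for c in col.cat.categories]
        if col.isna().any():
            bad = data.loc[col.isna(), variable]
            raise SchemaError(f"column {variable!r} has values outside declared levels")
        return cats
    vals = pd.unique(col)
    if pd.isna(vals).any():
        raise SchemaError(f"column {variable!r} contains missing values")
    return sorted(vals, key=str)


def _centering_transform(c: np.ndarray) -> np.ndarray:
    """Sparse-friendly basis of the null space of c': solve for one coefficient.

    Picks the pivot with the largest |c| for conditioning; the returned
    (k, k-1) matrix is the identity on the non-pivot coefficients with the
    pivot row filled so that c' Zc = 0 exactly.
    """
    k = c.size
    piv = int(np.argmax(np.abs(c)))
    keep = [j for j in range(k) if j != piv]
    Zc = np.zeros((k, k - 1))
    Zc[keep, np.arange(k - 1)] = 1.0
    Zc[piv, :] = -c[keep] / c[piv]
    return Zc


def build_design(data: pd.DataFrame, spec: VCMSpec) -> DesignBlocks:
    """Assemble constant and centred smooth design blocks for ``spec``.

    Dummy coding uses the declared reference levels; every smooth is
    centred (its sum over the observed waves is zero) through an absorbed
    linear constraint, which keeps the paired constant coefficient
    identifiable.  Rows align with ``data`` rows.
    """
    for t in spec.terms:
        if t.variable is not None and t.variable not in data.columns:
            raise SchemaError(f"column {t.variable!r} missing from data")
    for col in (spec.response, spec.modifier):
        if col not in data.columns:
            raise SchemaError(f"column {col!r} missing from data")

    n = len(data)
    y = np.asarray(data[spec.response], dtype=float)
    if spec.family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
        raise SchemaError("binomial response must be coded 0/1")
    t_vals = np.asarray(data[spec.modifier], dtype=float)
    waves = np.unique(t_vals)

    B_rows = bspline_basis(t_vals, spec.basis, sparse=True)
    B_grid = bspline_basis(waves, spec.basis)
    c = B_grid.sum(axis=0)  # column sums over unique waves
    Zc = _centering_transform(c)
    Zc_sp = sp.csr_array(Zc)
    S_full = penalty_matrix(spec.basis.n_basis, spec.penalty_order)
    S_c = Zc.T @ S_full @ Zc
    k1 = spec.basis.n_basis - 1

    const_cols: list[np.ndarray] = [np.ones(n)]
    column_index: list[tuple] = [("const", INTERCEPT, None)]
    smooth_parts: list[tuple] = []  # (variable, level, indicator or None)

    for term in spec.terms:
        if term.role == "varying_intercept":
            smooth_parts.append((None, None, None))
            continue
        levels = _levels_of(data, term.variable)
        if len(levels) < 2:
            raise DegenerateDesignError(
                f"variable {term.variable!r} has a single level"
            )
        ref = term.reference_level if term.reference_level is not None else levels[0]
        if ref not in levels:
            raise SchemaError(
                f"reference level {ref!r} not among levels of {term.variable!r}"
            )
        vals = np.asarray(data[term.variable])
        if term.role in {"constant", "varying"}:
            for lev in levels:
                if lev == ref:
                    continue
                d = (vals == lev).astype(float)
                if d.sum() == 0 or d.sum() == n:
                    raise DegenerateDesignError(
                        f"dummy for {term.variable!r}={lev!r} is constant"
                    )
                const_cols.append(d)
                column_index.append(("const", term.variable, lev))
        if term.role in {"varying", "smooth_only"}:
            for lev in levels:
                d = (vals == lev).astype(float)
                if d.sum() == 0:
                    raise DegenerateDesignError(
                        f"no observations for {term.variable!r}={lev!r}"
                    )
                smooth_parts.append((term.variable, lev, d))

    Z = sp.csr_array(np.column_stack(const_cols))
    n_const = Z.shape[1]

    mats = [Z]
    blocks: list[SmoothBlock] = []
    col = n_const
    for variable, level, d in smooth_parts:
        R = B_rows if d is None else B_rows.multiply(d[:, None]).tocsr()
        R = (R @ Zc_sp).tocsr()
        mats.append(R)
        blocks.append(SmoothBlock(variable, level, slice(col, col + k1), Zc, S_c))
        column_index.extend(
            ("smooth", variable, level) for _ in range(k1)
        )
        col += k1

    X = sp.hstack(mats, format="csr")
    return DesignBlocks(
        X=X, y=y, n_const=n_const, blocks=blocks, column_index=column_index,
        spec=spec, t=t_vals, waves=waves, basis_grid=B_grid,
    )


def align_penalties(design: DesignBlocks, penalties) -> np.ndarray:
    """Per-block smoothing parameters as an array aligned with design.blocks."""
    q = len(design.blocks)
    if penalties is None:
        return np.ones(q)
    if isinstance(penalties, (int, float)):
        return np.full(q, float(penalties))
    if len(penalties) != q:
        raise ValueError(
            f"{len(penalties)} penalties for {q} smooth blocks"
        )
    lams = np.array(
        [p.lam if isinstance(p, PenaltySpec) else float(p) for p in penalties]
    )
    if (lams < 0).any():
        raise ValueError("smoothing parameters must be nonnegative")
    return lams


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Converged penalized fit with posterior covariance and complexity."""

    beta: np.ndarray                 # all coefficients [constants | deltas]
    lam: np.ndarray                  # per-smooth smoothing parameters
    edf_per_term: dict               # label -> effective df (diag-sum convention)
    edf_total: float
    deviance: float
    loglik: float
    aic: float
    scale: float                     # phi (1 for binomial, RSS/(n-edf) Gaussian)
    n_obs: int
    converged: bool
    n_iter: int
    design: DesignBlocks
    XtWX: np.ndarray = field(repr=False, default=None)  # at convergence
    A_cho: tuple = field(repr=False, default=None)      # chol of X'WX + P
    ridge_used: float = 0.0
    deviance_trace: list = field(default_factory=list, repr=False)
    penalized_deviance_trace: list = field(default_factory=list, repr=False)
    _Vb: np.ndarray = field(repr=False, default=None)

    @property
    def Vb(self) -> np.ndarray:
        """Posterior covariance phi * (X'WX + P)^-1 (computed lazily).

        When the penalized normal matrix was numerically singular (pinned
        with a tiny ridge), the inverse is replaced by a rank-truncated
        pseudo-inverse: the unidentified null-space direction contributes
        zero variance rather than the meaningless 1/ridge.
        """
        if self._Vb is None:
            p = self.design.n_cols
            if self.ridge_used == 0.0:
                self._Vb = sla.cho_solve(self.A_cho, np.eye(p)) * self.scale
            else:
                A = self.XtWX + _penalty_dense(self.design, self.lam, p)
                ev, U = sla.eigh(A)
                keep = ev > 1e-9 * ev.max()
                inv = np.where(keep, 1.0 / np.where(keep, ev, 1.0), 0.0)
                self._Vb = (U * inv) @ U.T * self.scale
        return self._Vb

    @property
    def b_hat(self) -> np.ndarray:
        """Constant coefficients (intercept first)."""
        return self.beta[: self.design.n_const]

    def gamma_hat(self, block: SmoothBlock) -> np.ndarray:
        """Spline coefficients of a block in the original (uncentred) basis."""
        return block.Zc @ self.beta[block.sl]

    def smooth_values(self, block: SmoothBlock, t_grid=None) -> np.ndarray:
        """Centred smooth a_j(t) evaluated on a grid (default: the waves)."""
        d = self.design
        if t_grid is None:
            return d.basis_grid @ self.gamma_hat(block)
        B = bspline_basis(np.asarray(t_grid, dtype=float), d.spec.basis)
        return B @ self.gamma_hat(block)

    def model_id(self) -> str:
        return self.design.spec.describe()


def _block_label(b: SmoothBlock) -> str:
    if b.variable is None:
        return "s(t)"
    return f"s(t):{b.variable}={b.level}"


def _penalty_dense(design: DesignBlocks, lam: np.ndarray, p: int) -> np.ndarray:
    P = np.zeros((p, p))
    for b, lj in zip(design.blocks, lam):
        P[b.sl, b.sl] += lj * b.S
    return P


def _edf_parts(design, A_cho, XtWX):
    """Diagonal of the influence factor F = (X'WX + P)^-1 X'WX, by term."""
    F_diag = np.diagonal(sla.cho_solve(A_cho, XtWX)).copy()
    per_term = {"constants": float(F_diag[: design.n_const].sum())}
    for b in design.blocks:
        per_term[_block_label(b)] = float(F_diag[b.sl].sum())
    return per_term, float(F_diag.sum()), F_diag


def _chol_robust(A: np.ndarray):
    """Cholesky with a tiny escalating ridge fallback.

    A model with a varying intercept alongside full per-level smooth sets
    (or two such sets) is exactly singular in one penalty-null-space
    direction: a common linear trend can move freely between the smooth
    blocks without changing fit or penalty.  A ridge of ~1e-10 x mean
    diagonal pins that direction to the minimum-norm representative while
    leaving identified directions untouched.  Raises RankDeficiencyError
    only if escalation up to 1e-6 still fails.
    """
    try:
        return sla.cho_factor(A), 0.0
    except (np.linalg.LinAlgError, sla.LinAlgError):
        pass
    scale = np.trace(A) / A.shape[0]
    for eps in (1e-10, 1e-8, 1e-6):
        ridge = eps * scale
        try:
            cho = sla.cho_factor(A + ridge * np.eye(A.shape[0]))
        except (np.linalg.LinAlgError, sla.LinAlgError):
            continue
        logger.warning(
            "penalized normal matrix numerically singular (confounded "
            "smooth directions); pinned with ridge %.1e", ridge,
        )
        return cho, ridge
    raise RankDeficiencyError(
        "penalized normal matrix is singular; consider a larger "
        "smoothing parameter"
    )


def _model_aic(family_name, deviance, loglik, edf_total):
    if family_name == "binomial":
        return deviance + 2.0 * edf_total
    return -2.0 * loglik + 2.0 * (edf_total + 1.0)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def fit_gaussian(design: DesignBlocks, penalties=None) -> FitResult:
    """Penalized least squares: beta = (X'X + P)^-1 X'y.

    ``P = blockdiag(lambda_j D_d' D_d)`` on the smooth blocks and zero on
    the unpenalized constant columns.  The scale is estimated as
    RSS / (n - edf).
    """
    lam = align_penalties(design, penalties)
    X, y = design.X, design.y
    n, p = X.shape
    XtX, Xty = design.weighted_crossprod()
    A = XtX + _penalty_dense(design, lam, p)
    A_cho, ridge_used = _chol_robust(A)
    beta = sla.cho_solve(A_cho, Xty)
    resid = y - X @ beta
    rss = float(resid @ resid)
    per_term, edf_total, _ = _edf_parts(design, A_cho, XtX)
    phi = rss / max(n - edf_total, 1.0)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * phi)) - rss / (2.0 * phi)
    return FitResult(
        beta=beta, lam=lam, edf_per_term=per_term, edf_total=edf_total,
        deviance=rss, loglik=loglik,
        aic=_model_aic("gaussian", rss, loglik, edf_total),
        scale=phi, n_obs=n, converged=True, n_iter=1,
        design=design, XtWX=XtX, A_cho=A_cho, ridge_used=ridge_used,
        deviance_trace=[rss], penalized_deviance_trace=[rss],
    )


def _penalized_dev(design, lam, beta, dev):
    pen = 0.0
    for b, lj in zip(design.blocks, lam):
        d = beta[b.sl]
        pen += lj * float(d @ b.S @ d)
    return dev + pen


def fit_pirls(
    design: DesignBlocks,
    penalties=None,
    family: Family | None = None,
    beta0: np.ndarray | None = None,
    tol: float = PIRLS_TOL,
    maxit: int = PIRLS_MAXIT,
) -> FitResult:
    """Penalized IRLS / Fisher scoring for the generalized VCM.

    Maximizes the penalized log-likelihood l(gamma) - sum_j lambda_j
    ||D_d gamma_j||^2 by iterating weighted penalized least squares on the
    working response until the relative change in penalized deviance falls
    below ``tol``.  With the Gaussian family the first iteration reproduces
    :func:`fit_gaussian` exactly.  Step halving keeps the penalized
    deviance non-increasing.
    """
    if family is None:
        family = get_family(design.spec.family)
    if family.name == "gaussian":
        return fit_gaussian(design, penalties)

    lam = align_penalties(design, penalties)
    X, y = design.X, design.y
    n, p = X.shape
    P = _penalty_dense(design, lam, p)
    ridge = np.zeros(p)
    ridged = False

    if beta0 is not None:
        beta = np.asarray(beta0, dtype=float).copy()
        eta = X @ beta
        mu = family.linkinv(eta)
        dev = family.deviance(y, mu)
        pdev = _penalized_dev(design, lam, beta, dev)
        dev_trace, pdev_trace = [dev], [pdev]
    else:
        # heuristic start: not a coefficient-based fit, so its "deviance"
        # does not enter the monotonicity guard or the traces
        beta = np.zeros(p)
        mu = (y + 0.5) / 2.0
        eta = family.link(mu)
        dev = family.deviance(y, mu)
        pdev = np.inf
        dev_trace, pdev_trace = [], []
    A_cho = None
    XtWX = None
    converged = False

    for it in range(1, maxit + 1):
        w = family.variance(mu)
        w = np.clip(w, 1e-10, None)
        z = eta + (y - mu) / w
        XtWX, XtWz = design.weighted_crossprod(w, z)
        A = XtWX + P + np.diag(ridge)
        A_cho, ridge_used = _chol_robust(A)
        beta_new = sla.cho_solve(A_cho, XtWz)

        # step halving: never let the penalized deviance increase
        step = 1.0
        for _ in range(30):
            cand = beta + step * (beta_new - beta)
            eta_c = X @ cand
            mu_c = family.linkinv(eta_c)
            mu_c = np.clip(mu_c, 1e-12, 1 - 1e-12)
            dev_c = family.deviance(y, mu_c)
            pdev_c = _penalized_dev(design, lam, cand, dev_c)
            if np.isfinite(pdev_c) and (
                not np.isfinite(pdev)
                or pdev_c <= pdev + 1e-12 * (abs(pdev) + 1.0)
            ):
                break
            step *= 0.5
        beta, eta, mu, dev, pdev_new = cand, eta_c, mu_c, dev_c, pdev_c
        dev_trace.append(dev)
        pdev_trace.append(pdev_new)

        if not ridged and np.mean(np.abs(eta) > QUASI_SEP_ETA) > QUASI_SEP_FRAC:
            logger.warning(
                "quasi-separation suspected (|eta|>%.0f for >%.0f%% of rows); "
                "applying ridge %.0e to the constant block",
                QUASI_SEP_ETA, 100 * QUASI_SEP_FRAC, CONST_RIDGE,
            )
            ridge[: design.n_const] = CONST_RIDGE
            ridged = True

        if abs(pdev - pdev_new) <= tol * (abs(pdev_new) + 0.1):
            pdev = pdev_new
            converged = True
            break
        pdev = pdev_new

    if not converged:
        raise ConvergenceError(
            f"Fisher scoring did not converge in {maxit} iterations",
            trace=dev_trace,
        )

    per_term, edf_total, _ = _edf_parts(design, A_cho, XtWX)
    phi = family.scale_fixed if family.scale_fixed is not None else dev / (n - edf_total)
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    return FitResult(
        beta=beta, lam=lam, edf_per_term=per_term, edf_total=edf_total,
        deviance=dev, loglik=loglik,
        aic=_model_aic(family.name, dev, loglik, edf_total),
        scale=phi, n_obs=n, converged=converged, n_iter=it,
        design=design, XtWX=XtWX, A_cho=A_cho, ridge_used=ridge_used,
        deviance_trace=dev_trace, penalized_deviance_trace=pdev_trace,
    )


# ---------------------------------------------------------------------------
# smoothing-parameter selection
# ---------------------------------------------------------------------------

def gcv_score(fit: FitResult) -> float:
    """Generalized cross validation: n * deviance / (n - edf)^2."""
    denom = fit.n_obs - fit.edf_total
    if denom <= 0:
        return np.inf
    return fit.n_obs * fit.deviance / denom**2


def _logdet_plus(M: np.ndarray, tol: float = 1e-10) -> tuple[float, int]:
    ev = sla.eigvalsh(M)
    pos = ev[ev > tol * max(ev.max(), 1.0)]
    return float(np.sum(np.log(pos))), len(pos)


def reml_score(fit: FitResult, _cache={}) -> float:
    """Negative Laplace-approximate restricted likelihood (smaller is better)."""
    design, lam = fit.design, fit.lam
    p = design.n_cols
    P = _penalty_dense(design, lam, p)
    A = fit.XtWX / fit.scale + P
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    logdet_P = 0.0
    rank_P = 0
    for b, lj in zip(design.blocks, lam):
        key = id(b.S)
        if key not in _cache:
            _cache[key] = _logdet_plus(b.S)
        ld, r = _cache[key]
        if lj <= 0:
            return np.inf
        logdet_P += ld + r * np.log(lj)
        rank_P += r
    pen = _penalized_dev(design, lam, fit.beta, 0.0)
    lp = fit.loglik - 0.5 * pen / fit.scale
    return -(lp + 0.5 * logdet_P - 0.5 * logdet_A + 0.5 * rank_P * np.log(2 * np.pi))


def select_lambda(
    design: DesignBlocks,
    family: Family | None = None,
    method: str = "gcv",
    grid: np.ndarray = LAMBDA_GRID,
    refine: bool = True,
    max_refine_evals: int | None = None,
) -> tuple[np.ndarray, FitResult]:
    """Choose per-smooth smoothing parameters by GCV or approximate REML.

    A shared-lambda sweep over a deterministic log10 grid is followed by a
    Nelder–Mead refinement jointly over all per-term log-lambdas.  Fits are
    warm-started along the search.  Returns the selected lambdas and the
    corresponding fit.
    """
    if not design.blocks:
        raise SelectionError("no penalized smooth blocks to select lambda for")
    if family is None:
        family = get_family(design.spec.family)
    if method not in {"gcv", "reml"}:
        raise ValueError(f"unknown lambda-selection method {method!r}")
    q = len(design.blocks)
    crit = gcv_score if method == "gcv" else reml_score

    state = {"beta": None}

    def evaluate(loglam: np.ndarray) -> tuple[float, FitResult]:
        lam = 10.0 ** np.clip(loglam, *LOGLAM_BOUNDS)
        try:
            fit = fit_pirls(design, lam, family, beta0=state["beta"])
        except (RankDeficiencyError, ConvergenceError):
            return np.inf, None
        state["beta"] = fit.beta
        return crit(fit), fit

    best = (np.inf, None, None)
    for lg in grid:
        score, fit = evaluate(np.full(q, lg))
        if score < best[0]:
            best = (score, np.full(q, float(lg)), fit)
    if not np.isfinite(best[0]):
        raise SelectionError(
            f"{method} criterion non-finite across the whole lambda grid"
        )

    if refine:
        cache = {}

        def objective(x):
            key = tuple(np.round(x, 10))
            if key not in cache:
                cache[key] = evaluate(np.asarray(x))
            return cache[key][0]

        maxfev = max_refine_evals if max_refine_evals is not None else min(40 * q, 120)
        res = minimize(
            objective, best[1], method="Nelder-Mead",
            options={"xatol": 0.05, "fatol": 1e-6 * (abs(best[0]) + 1.0),
                     "maxfev": maxfev, "disp": False},
        )
        x_best = np.clip(res.x, *LOGLAM_BOUNDS)
        score, fit = evaluate(x_best)
        if np.isfinite(score) and score <= best[0]:
            best = (score, x_best, fit)

    lam = 10.0 ** best[1]
    # refit cleanly at the selected lambda (cold start) for reproducibility
    final = fit_pirls(design, lam, family)
    return lam, final
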