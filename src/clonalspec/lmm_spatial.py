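"""Univariate spatial mixed model for clonal field trials.

Model: ``y = X beta + Z c + e`` with a fixed part made of an overall mean
plus optional second-order orthogonal polynomials in the row and column
indices, a random clone effect ``c ~ N(0, sigma2_c I)``, and residuals that
are either iid (``R = sigma2 I``) or a separable first-order autoregressive
process over the planting grid
(``R = sigma2 [AR1(rho_col) (x) AR1(rho_row)]``, restricted to the observed
positions).

Estimation is REML. The fixed effects and the residual scale ``sigma2`` are
profiled out analytically, and a bounded multi-start Powell search runs over
the remaining parameters (the variance ratio ``gamma = sigma2_c/sigma2`` and
the autocorrelations). The asymptotic variance-covariance of the variance
parameters comes from the numerically differenced Hessian of the restricted
log-likelihood at the optimum, which feeds the delta-method standard error of
the broad-sense heritability ``H2 = sigma2_c / (sigma2_c + sigma2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sp_linalg
from scipy import optimize, stats

from .synth_trial import TrialLayout

RHO_BOUND = 0.99
GAMMA_MAX = 1e3

STRUCTURES = ("iid", "ar1xar1")


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class RankError(ValueError):
    """Fixed-effect design is rank deficient or degenerate."""


class ComparabilityError(ValueError):
    """Fits are not comparable (different fixed parts under REML)."""


# ---------------------------------------------------------------------------
# design pieces


def orthogonal_polynomial_basis(indices: Sequence[float], degree: int = 2) -> np.ndarray:
    """Orthonormal polynomial basis (without the constant) over ``indices``.

    Columns are mutually orthogonal with unit norm; the first spans the
    linear trend of the centered indices, the second adds the quadratic.
    """
    x = np.asarray(indices, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if np.unique(x).size < degree + 1:
        raise RankError(
            f"need at least {degree + 1} distinct index values for degree {degree}"
        )
    xc = x - x.mean()
    M = np.column_stack([xc**k for k in range(1, degree + 1)])
    # orthogonalize against the constant as well, then among themselves
    M -= M.mean(axis=0)
    Q, R = np.linalg.qr(M)
    if np.any(np.abs(np.diag(R)) < 1e-12 * max(1.0, np.abs(R).max())):
        raise RankError("polynomial basis is rank deficient")
    # sign convention: positive correlation with increasing index power
    signs = np.sign(np.diag(R))
    return Q * signs


def ar1_correlation(rho: float, indices: Sequence[int]) -> np.ndarray:
    """AR1 correlation matrix: entry (i, j) = rho**|index_i - index_j|."""
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    idx = np.asarray(indices)
    lags = np.abs(np.subtract.outer(idx, idx))
    return np.asarray(float(rho) ** lags, dtype=float)


def residual_covariance(
    params: dict, layout: TrialLayout, structure: str = "ar1xar1"
) -> np.ndarray:
    """Residual covariance of the observed trees.

    For ``"ar1xar1"`` the entry for trees at (r1,c1) and (r2,c2) is
    ``sigma2 * rho_col**|c1-c2| * rho_row**|r1-r2|`` — the observed-tree
    submatrix of the full Kronecker product; ``"iid"`` gives
    ``sigma2 * I``.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown residual structure {structure!r}")
    sigma2 = float(params["sigma2"])
    n = layout.n_trees
    if structure == "iid":
        return sigma2 * np.eye(n)
    rows = layout.table["row"].to_numpy()
    cols = layout.table["col"].to_numpy()
    cr = float(params["rho_row"]) ** np.abs(np.subtract.outer(rows, rows))
    cc = float(params["rho_col"]) ** np.abs(np.subtract.outer(cols, cols))
    return sigma2 * cr * cc


# ---------------------------------------------------------------------------
# model specification and fit containers


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response name, fixed polynomials, clone effect, residuals."""

    response: str
    row_poly: bool = True
    col_poly: bool = True
    degree: int = 2
    clone_effect: bool = True
    residual: str = "ar1xar1"

    def __post_init__(self):
        if self.residual not in STRUCTURES:
            raise ValueError(f"unknown residual structure {self.residual!r}")
        if self.degree > 2:
            raise ValueError("polynomial degree is capped at 2")


@dataclass
class UnivariateFit:
    """REML estimates of the univariate spatial model."""

    spec: ModelSpec
    sigma2_c: float
    sigma2: float
    rho_row: float | None
    rho_col: float | None
    beta: np.ndarray
    fixed_terms: dict[str, slice]
    loglik: float
    converged: bool
    n_obs: int
    n_fixed: int
    varpar_names: tuple[str, ...]
    trace: list[float] = field(default_factory=list, repr=False)
    _vcov: np.ndarray | None = field(default=None, repr=False)
    _problem: "_REMLProblem | None" = field(default=None, repr=False)
    _beta_cov: np.ndarray | None = field(default=None, repr=False)

    def varpar_values(self) -> np.ndarray:
        vals = {"sigma2_c": self.sigma2_c, "sigma2": self.sigma2,
                "rho_row": self.rho_row, "rho_col": self.rho_col}
        return np.array([vals[k] for k in self.varpar_names], dtype=float)

    def vcov(self) -> np.ndarray:
        """Asymptotic variance-covariance of the variance parameters
        (rows/cols ordered as ``varpar_names``), from the numerically
        differenced Hessian of the restricted log-likelihood."""
        if self._vcov is None:
            if self._problem is None:
                raise RuntimeError("fit carries no likelihood machinery")
            self._vcov = self._problem.varpar_vcov(self.varpar_values(), self.varpar_names)
        return self._vcov

    def fixed_signature(self) -> tuple:
        return (self.spec.row_poly, self.spec.col_poly, self.spec.degree, self.n_fixed)


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Broad-sense heritability with delta-method SE and clone-variance LRT p."""

    h2: float
    se: float
    p_clone: float | None = None


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p: float
    boundary: bool


@dataclass(frozen=True)
class WaldFResult:
    term: str
    f: float
    df1: int
    df2: int
    p: float


# ---------------------------------------------------------------------------
# REML internals


class _REMLProblem:
    """Dense-matrix REML machinery for one response on one layout."""

    def __init__(self, y: np.ndarray, X: np.ndarray, layout: TrialLayout, spec: ModelSpec):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.spec = spec
        rows = layout.table["row"].to_numpy()
        cols = layout.table["col"].to_numpy()
        self.row_lags = np.abs(np.subtract.outer(rows, rows))
        self.col_lags = np.abs(np.subtract.outer(cols, cols))
        clones = layout.table["clone_id"].to_numpy()
        self.same_clone = (clones[:, None] == clones[None, :]).astype(float)
        _, logdet_xtx = np.linalg.slogdet(self.X.T @ self.X)
        self.half_logdet_xtx = 0.5 * logdet_xtx

    # -- correlation builders -------------------------------------------------
    def _resid_corr(self, rho_row: float, rho_col: float) -> np.ndarray:
        if self.spec.residual == "iid":
            return np.eye(self.n)
        return (float(rho_row) ** self.row_lags) * (float(rho_col) ** self.col_lags)

    # -- profiled restricted likelihood --------------------------------------
    def profiled(self, theta: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
        """Profiled REML at theta = (gamma[, rho_row, rho_col]).

        Returns (loglik, sigma2_hat, beta_hat, (X'W^-1 X)^-1).
        """
        theta = list(theta)
        gamma = theta.pop(0) if self.spec.clone_effect else 0.0
        rho_row, rho_col = theta if self.spec.residual == "ar1xar1" else (0.0, 0.0)
        W = self._resid_corr(rho_row, rho_col)
        if self.spec.clone_effect:
            W = W + gamma * self.same_clone
        try:
            L = sp_linalg.cholesky(W, lower=True, check_finite=False)
        except sp_linalg.LinAlgError:
            return -np.inf, np.nan, np.full(self.p, np.nan), np.full((self.p, self.p), np.nan)
        logdet_w = 2.0 * np.sum(np.log(np.diag(L)))
        Xw = sp_linalg.solve_triangular(L, self.X, lower=True, check_finite=False)
        yw = sp_linalg.solve_triangular(L, self.y, lower=True, check_finite=False)
        xtx = Xw.T @ Xw
        sign, logdet_x = np.linalg.slogdet(xtx)
        if sign <= 0:
            raise RankError("fixed-effect design singular under current covariance")
        xtx_inv = np.linalg.inv(xtx)
        beta = xtx_inv @ (Xw.T @ yw)
        resid = yw - Xw @ beta
        quad = float(resid @ resid)
        nmp = self.n - self.p
        if quad <= 0:
            return -np.inf, 0.0, beta, xtx_inv
        sigma2 = quad / nmp
        ll = (
            -0.5 * (nmp * (np.log(sigma2) + 1.0 + np.log(2.0 * np.pi)) + logdet_w + logdet_x)
            + self.half_logdet_xtx
        )
        return ll, sigma2, beta, xtx_inv

    def profiled_loglik(self, theta: np.ndarray) -> float:
        return self.profiled(np.asarray(theta, dtype=float))[0]

    # -- unprofiled restricted likelihood (for Hessians and oracles) ---------
    def reml_loglik(self, varpars: dict[str, float]) -> float:
        """Restricted log-likelihood at explicit variance parameters."""
        sigma2 = float(varpars["sigma2"])
        if sigma2 <= 0:
            return -np.inf
        V = sigma2 * self._resid_corr(varpars.get("rho_row", 0.0), varpars.get("rho_col", 0.0))
        if self.spec.clone_effect:
            V = V + float(varpars.get("sigma2_c", 0.0)) * self.same_clone
        return reml_loglik_dense(self.y, self.X, V)

    def varpar_vcov(self, values: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
        """Inverse negative Hessian by central differences, step 1e-4 x scale.

        Variance parameters are floored slightly above zero before
        differencing so boundary estimates (sigma2_c = 0) stay evaluable.
        """
        theta0 = values.copy()
        scale = np.maximum(np.abs(theta0), 1e-3)
        floor = 1e-6 * max(theta0[names.index("sigma2")], 1e-6)
        for i, name in enumerate(names):
            if name.startswith("sigma2") and theta0[i] < floor:
                theta0[i] = floor

        def f(th):
            return self.reml_loglik(dict(zip(names, th)))

        k = len(theta0)
        h = 1e-4 * scale
        H = np.empty((k, k))
        f0 = f(theta0)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    H[i, i] = (f(theta0 + ei) - 2.0 * f0 + f(theta0 - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(theta0 + ei + ej) - f(theta0 + ei - ej)
                        - f(theta0 - ei + ej) + f(theta0 - ei - ej)
                    ) / (4.0 * h[i] * h[j])
        info = -H
        # PSD repair: clip non-positive curvature directions
        w, v = np.linalg.eigh((info + info.T) / 2.0)
        w = np.clip(w, 1e-10, None)
        return (v / w) @ v.T


def reml_loglik_dense(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float:
    """Restricted log-likelihood with the full covariance ``V`` supplied.

    Patterson-Thompson form, evaluated via Cholesky:
    ``ll = -1/2 [log|V| + log|X'V^-1 X| - log|X'X| + y'Py + (n-p) log 2pi]``
    with ``P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1``. The ``log|X'X|`` term
    makes the value equal the Gaussian log-density of any orthonormal
    error-contrast projection ``K'y`` (K a basis of the null space of X'),
    so it is invariant to the fixed-effect basis.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    L = sp_linalg.cholesky(V, lower=True, check_finite=False)
    logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
    Xw = sp_linalg.solve_triangular(L, X, lower=True, check_finite=False)
    yw = sp_linalg.solve_triangular(L, y, lower=True, check_finite=False)
    xtx = Xw.T @ Xw
    sign, logdet_x = np.linalg.slogdet(xtx)
    if sign <= 0:
        raise RankError("X'V^-1X singular")
    beta = np.linalg.solve(xtx, Xw.T @ yw)
    resid = yw - Xw @ beta
    quad = float(resid @ resid)
    _, logdet_xtx0 = np.linalg.slogdet(X.T @ X)
    return -0.5 * (
        logdet_v + logdet_x - logdet_xtx0 + quad + (n - p) * np.log(2.0 * np.pi)
    )


def build_design(layout: TrialLayout, spec: ModelSpec) -> tuple[np.ndarray, dict[str, slice]]:
    """Fixed-effect design: intercept plus optional row/col orthogonal polys."""
    n = layout.n_trees
    blocks = [np.ones((n, 1))]
    terms = {"intercept": slice(0, 1)}
    pos = 1
    if spec.row_poly:
        B = orthogonal_polynomial_basis(layout.table["row"].to_numpy(), spec.degree)
        blocks.append(B)
        terms["row_poly"] = slice(pos, pos + B.shape[1])
        pos += B.shape[1]
    if spec.col_poly:
        B = orthogonal_polynomial_basis(layout.table["col"].to_numpy(), spec.degree)
        blocks.append(B)
        terms["col_poly"] = slice(pos, pos + B.shape[1])
        pos += B.shape[1]
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankError("fixed-effect design is rank deficient")
    return X, terms


_DEFAULT_STARTS_AR1 = (
    (0.1, 0.0, 0.0),
    (1.0, 0.0, 0.0),
    (3.0, 0.0, 0.0),
    (1.0, 0.5, 0.5),
    (1.0, -0.5, -0.5),
)
_DEFAULT_STARTS_IID = ((0.1,), (1.0,), (3.0,))


def reml_fit(
    y: pd.Series,
    spec: ModelSpec,
    layout: TrialLayout,
    starts: Sequence[Sequence[float]] | None = None,
    ftol: float = 1e-9,
    n_polish: int = 2,
) -> UnivariateFit:
    """Fit the univariate spatial mixed model by REML.

    ``y`` is indexed by tree id; trees with missing responses are dropped
    listwise (the layout is subset accordingly, so spatial lags among the
    remaining trees are preserved). Multi-start bounded Powell search over
    the profiled likelihood: the start grid is ranked by likelihood and the
    best ``n_polish`` starts are polished to convergence. ``starts``
    overrides the default grid.
    """
    y = y.dropna()
    if y.index.duplicated().any():
        raise ValueError("duplicated tree ids in response")
    sub = layout.subset(y.index)
    if sub.n_trees != len(y):
        raise ValueError("response contains tree ids absent from the layout")
    yv = y.reindex(sub.table["tree_id"]).to_numpy(dtype=float)

    X, terms = build_design(sub, spec)
    prob = _REMLProblem(yv, X, sub, spec)

    if spec.clone_effect:
        if spec.residual == "ar1xar1":
            bounds = [(0.0, GAMMA_MAX), (-RHO_BOUND, RHO_BOUND), (-RHO_BOUND, RHO_BOUND)]
            start_list = starts or _DEFAULT_STARTS_AR1
        else:
            bounds = [(0.0, GAMMA_MAX)]
            start_list = starts or _DEFAULT_STARTS_IID
    else:
        if spec.residual == "ar1xar1":
            bounds = [(-RHO_BOUND, RHO_BOUND), (-RHO_BOUND, RHO_BOUND)]
            start_list = starts or ((0.0, 0.0), (0.5, 0.5), (-0.5, -0.5))
        else:
            bounds = []
            start_list = ()

    trace: list[float] = []
    if not bounds:  # no clone effect, iid residuals: closed-form OLS/REML
        ll, sigma2, beta, xtx_inv = _profiled_ols(prob)
        best_theta = np.empty(0)
        converged = True
        trace.append(ll)
    else:
        def objective(th):
            val = prob.profiled_loglik(th)
            if not np.isfinite(val):
                return 1e12
            if not trace or val > trace[-1]:
                trace.append(val)
            return -val

        # rank the start grid by profiled likelihood, polish the best ones
        ranked = sorted(start_list, key=lambda s: -prob.profiled_loglik(np.asarray(s, dtype=float)))
        best = None
        converged = False
        for s in ranked[:max(1, n_polish)]:
            res = optimize.minimize(
                objective, np.asarray(s, dtype=float), method="Powell",
                bounds=bounds, options={"xtol": 1e-5, "ftol": ftol, "maxiter": 200},
            )
            if best is None or res.fun < best.fun:
                best = res
                converged = bool(res.success) or converged
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("REML optimization failed", last_iterate=best)
        best_theta = np.atleast_1d(best.x)
        ll, sigma2, beta, xtx_inv = prob.profiled(best_theta)
        if not np.isfinite(ll):
            raise ConvergenceError("REML optimum not finite", last_iterate=best_theta)

    if spec.clone_effect:
        gamma = best_theta[0] if bounds else 0.0
        sigma2_c = float(gamma * sigma2)
        rest = best_theta[1:]
    else:
        sigma2_c = 0.0
        rest = best_theta
    if spec.residual == "ar1xar1":
        rho_row, rho_col = (float(rest[0]), float(rest[1])) if len(rest) == 2 else (0.0, 0.0)
    else:
        rho_row = rho_col = None

    names: list[str] = []
    if spec.clone_effect:
        names.append("sigma2_c")
    names.append("sigma2")
    if spec.residual == "ar1xar1":
        names += ["rho_row", "rho_col"]

    fit = UnivariateFit(
        spec=spec,
        sigma2_c=sigma2_c,
        sigma2=float(sigma2),
        rho_row=rho_row,
        rho_col=rho_col,
        beta=beta,
        fixed_terms=terms,
        loglik=float(ll),
        converged=converged,
        n_obs=prob.n,
        n_fixed=prob.p,
        varpar_names=tuple(names),
        trace=trace,
        _problem=prob,
        _beta_cov=sigma2 * xtx_inv,
    )
    return fit


def _profiled_ols(prob: _REMLProblem) -> tuple[float, float, np.ndarray, np.ndarray]:
    """REML (= residual-df OLS) solution with no random effects beyond iid error."""
    X, y = prob.X, prob.y
    n, p = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    # log|X'X| from the profiled form cancels against the basis-invariance term
    ll = -0.5 * (n - p) * (np.log(sigma2) + 1.0 + np.log(2.0 * np.pi))
    return ll, sigma2, beta, xtx_inv


# ---------------------------------------------------------------------------
# tests on fits


def likelihood_ratio_test(
    fit_full: UnivariateFit | "object",
    fit_reduced: UnivariateFit | "object",
    boundary: bool = False,
    df: int | None = None,
) -> LRTResult:
    """LRT between nested REML fits with identical fixed parts.

    ``boundary=True`` applies the 50:50 mixture of a point mass at zero and a
    chi-square (the reference for a variance tested on its boundary, e.g.
    ``sigma2_c = 0``); otherwise a plain chi-square with ``df`` equal to the
    difference in variance-parameter counts.
    """
    if fit_full.fixed_signature() != fit_reduced.fixed_signature():
        raise ComparabilityError("REML fits with different fixed parts are not comparable")
    if df is None:
        df = len(fit_full.varpar_names) - len(fit_reduced.varpar_names)
    if df < 1:
        raise ValueError("full model must have more variance parameters")
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    if stat == 0.0:
        p = 1.0
    elif boundary:
        if df != 1:
            raise ValueError("boundary mixture implemented for df = 1")
        p = 0.5 * stats.chi2.sf(stat, 1)
    else:
        p = float(stats.chi2.sf(stat, df))
    return LRTResult(statistic=float(stat), df=df, p=float(p), boundary=boundary)


def wald_f_test(fit: UnivariateFit, term: str) -> WaldFResult:
    """Approximate Wald F-test for a fixed term.

    Uses the GLS coefficient covariance at the fitted variance parameters;
    denominator degrees of freedom are the containment-style simplification
    ``n - rank(X)``.
    """
    if term not in fit.fixed_terms:
        raise KeyError(f"term {term!r} not in fixed part {sorted(fit.fixed_terms)}")
    sl = fit.fixed_terms[term]
    b = fit.beta[sl]
    C = fit._beta_cov[sl, sl]
    q = len(b)
    sign, _ = np.linalg.slogdet(C)
    if sign <= 0 or np.linalg.cond(C) > 1e12:
        raise RankError(f"coefficient covariance for {term!r} is singular")
    f = float(b @ np.linalg.solve(C, b)) / q
    df2 = fit.n_obs - fit.n_fixed
    p = float(stats.f.sf(f, q, df2))
    return WaldFResult(term=term, f=f, df1=q, df2=df2, p=p)


def heritability(fit: UnivariateFit, p_clone: float | None = None) -> HeritabilityEstimate:
    """Broad-sense heritability ``H2 = sigma2_c/(sigma2_c + sigma2)``.

    The SE is first-order delta method: gradient
    ``(sigma2, -sigma2_c)/(sigma2_c + sigma2)**2`` applied to the fit's
    variance-parameter covariance.
    """
    if "sigma2_c" not in fit.varpar_names:
        raise ValueError("fit has no clone variance component")
    total = fit.sigma2_c + fit.sigma2
    if total <= 0:
        raise ZeroDivisionError("total variance is zero; heritability undefined")
    h2 = fit.sigma2_c / total
    grad = np.array([fit.sigma2, -fit.sigma2_c]) / total**2
    V = fit.vcov()
    i_c = fit.varpar_names.index("sigma2_c")
    i_e = fit.varpar_names.index("sigma2")
    sub = V[np.ix_([i_c, i_e], [i_c, i_e])]
    se = float(np.sqrt(max(0.0, grad @ sub @ grad)))
    return HeritabilityEstimate(h2=float(h2), se=se, p_clone=p_clone)
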