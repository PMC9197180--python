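"""Stacked bivariate mixed model for genetic correlations between traits.

The two responses are stacked into one vector with a trait factor. Fixed
effects are the trait means and second-order orthogonal row/column
polynomials nested within trait. Random effects are the clone effect nested
within trait, ``tc ~ N(0, Gc (x) Ic)`` with ``Gc`` an unstructured 2x2
clonal covariance, and a tree (experimental-unit) effect
``u ~ N(0, sigma2_u I)`` shared across traits, which carries the
within-tree cross-trait dependence. Residuals are block diagonal with a
separate separable AR1xAR1 (or iid) process per trait; residual cross-trait
covariance is zero by construction.

The genetic correlation is ``r_g = Gc12 / sqrt(Gc11 Gc22)``; its SE comes
from the delta method on the variance-parameter covariance, and estimates
pinned to the parameter boundary (|r_g| > 0.999) are clamped and flagged
"B" with no SE, following the reporting convention for boundary REML
solutions.

Numerics: ``Gc`` is parameterized through its Cholesky factor so it stays
positive semi-definite during optimization, responses are standardized
internally so both traits enter on comparable scales, and the search is a
bounded quasi-Newton (L-BFGS-B) warm-started from the two univariate fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lmm_spatial import (
    ConvergenceError,
    RHO_BOUND,
    _REMLProblem,  # reused for lag/incidence precomputation only
    ModelSpec,
    orthogonal_polynomial_basis,
    reml_fit,
    reml_loglik_dense,
)
from .synth_trial import TrialLayout

BOUNDARY_RG = 0.999
_MIN_CLONAL_VAR = 1e-5  # on the standardized-response scale
_MIN_RESID = 1e-2  # standardized-scale floor keeping V away from singularity


class OverlapError(ValueError):
    """The two traits share no trees."""


class UndefinedCorrelationError(ValueError):
    """A clonal variance is (numerically) zero; r_g is undefined."""


class InestimableGcError(ValueError):
    """No clone has two or more ramets; Gc cannot be separated from trees."""


# ---------------------------------------------------------------------------
# stacking


@dataclass(frozen=True)
class StackedBivariate:
    """Two responses stacked with a trait factor, plus design matrices.

    ``y`` holds trait-1 records then trait-2 records for the same ordered
    tree set; ``X`` carries trait means and trait-nested polynomials.
    """

    y: np.ndarray
    X: np.ndarray
    layout: TrialLayout  # subset covering the overlapping trees, in y order
    trait_names: tuple[str, str]
    n_trees: int
    frame: pd.DataFrame = field(repr=False)

    @property
    def n_records(self) -> int:
        return 2 * self.n_trees


def stack_bivariate(
    y1: pd.Series, y2: pd.Series, layout: TrialLayout,
    trait_names: tuple[str, str] | None = None,
    row_poly: bool = True, col_poly: bool = True, degree: int = 2,
) -> StackedBivariate:
    """Stack two per-tree responses into the bivariate design.

    Trees with either trait missing are dropped listwise; disjoint tree sets
    raise :class:`OverlapError`.
    """
    if trait_names is None:
        trait_names = (str(y1.name or "trait1"), str(y2.name or "trait2"))
    common = y1.dropna().index.intersection(y2.dropna().index)
    common = [t for t in layout.table["tree_id"] if t in set(common)]
    if len(common) == 0:
        raise OverlapError("traits measured on disjoint tree sets")
    sub = layout.subset(common)
    order = sub.table["tree_id"]
    v1 = y1.reindex(order).to_numpy(dtype=float)
    v2 = y2.reindex(order).to_numpy(dtype=float)
    n = len(order)
    y = np.concatenate([v1, v2])

    rows = sub.table["row"].to_numpy()
    cols = sub.table["col"].to_numpy()
    polys = []
    if row_poly:
        polys.append(orthogonal_polynomial_basis(rows, degree))
    if col_poly:
        polys.append(orthogonal_polynomial_basis(cols, degree))
    P = np.hstack(polys) if polys else np.empty((n, 0))
    zero = np.zeros_like(P)
    ones = np.ones((n, 1))
    zcol = np.zeros((n, 1))
    X = np.block([[ones, zcol, P, zero], [zcol, ones, zero, P]])

    frame = pd.DataFrame(
        {
            "tree_id": np.tile(order.to_numpy(), 2),
            "trait": np.repeat(list(trait_names), n),
            "value": y,
            "row": np.tile(rows, 2),
            "col": np.tile(cols, 2),
            "clone_id": np.tile(sub.table["clone_id"].to_numpy(), 2),
        }
    )
    return StackedBivariate(y=y, X=X, layout=sub, trait_names=tuple(trait_names),
                            n_trees=n, frame=frame)


# ---------------------------------------------------------------------------
# fit containers


@dataclass
class BivariateFit:
    """REML estimates of the stacked bivariate model (original trait scale)."""

    trait_names: tuple[str, str]
    Gc: np.ndarray  # 2x2 clonal covariance
    sigma2_u: float
    resid1: dict[str, float]  # sigma2 (+ rho_row, rho_col for ar1xar1)
    resid2: dict[str, float]
    loglik: float
    converged: bool
    n_records: int
    residual: str
    _machinery: "_BivariateProblem | None" = field(default=None, repr=False)
    _scale: np.ndarray | None = field(default=None, repr=False)  # (sd1, sd2)
    _vcov_G: np.ndarray | None = field(default=None, repr=False)

    def vcov_G(self) -> np.ndarray:
        """Delta-method covariance of (Gc11, Gc12, Gc22), original scale.

        Computed from the numerically differenced Hessian of the restricted
        log-likelihood in the (G11, G12, G22, sigma2_u, residual...)
        parameterization, inverted jointly and restricted to the Gc block.
        """
        if self._vcov_G is None:
            if self._machinery is None:
                raise RuntimeError("fit carries no likelihood machinery")
            vc_std = self._machinery.vcov_G_std()
            d1, d2 = self._scale
            J = np.diag([d1 * d1, d1 * d2, d2 * d2])  # G_orig = D G_std D
            self._vcov_G = J @ vc_std @ J
        return self._vcov_G


@dataclass(frozen=True)
class GeneticCorrelation:
    """Genetic correlation with SE, boundary flag, and optional LRT p."""

    r_g: float
    se: float | None
    boundary: bool
    p: float | None = None

    @property
    def flag(self) -> str:
        return "B" if self.boundary else ""


# ---------------------------------------------------------------------------
# likelihood machinery


class _BivariateProblem:
    """Dense REML for the stacked model on the standardized scale."""

    def __init__(self, stacked: StackedBivariate, residual: str = "ar1xar1"):
        self.residual = residual
        sub = stacked.layout
        n = stacked.n_trees
        self.n = n
        counts = sub.clone_counts()
        if (counts < 2).all():
            raise InestimableGcError("every clone has a single ramet; Gc inestimable")
        v1 = stacked.y[:n]
        v2 = stacked.y[n:]
        self.scale = np.array([np.std(v1) or 1.0, np.std(v2) or 1.0])
        self.y = np.concatenate([v1 / self.scale[0], v2 / self.scale[1]])
        self.X = stacked.X
        uni = _REMLProblem(self.y[:n], np.ones((n, 1)), sub,
                           ModelSpec("x", residual=residual))
        self.S = uni.same_clone
        self.row_lags = uni.row_lags
        self.col_lags = uni.col_lags
        self.I = np.eye(n)

    def _resid_corr(self, rho_row: float, rho_col: float) -> np.ndarray:
        if self.residual == "iid":
            return self.I
        return (float(rho_row) ** self.row_lags) * (float(rho_col) ** self.col_lags)

    def covariance_from_G(self, th: np.ndarray) -> np.ndarray:
        """V from (G11, G12, G22, s2u, s21[, rr1, rc1], s22[, rr2, rc2])."""
        if self.residual == "ar1xar1":
            g11, g12, g22, s2u, s21, rr1, rc1, s22, rr2, rc2 = th
        else:
            g11, g12, g22, s2u, s21, s22 = th
            rr1 = rc1 = rr2 = rc2 = 0.0
        S, I, n = self.S, self.I, self.n
        V = np.empty((2 * n, 2 * n))
        V[:n, :n] = g11 * S + s2u * I + s21 * self._resid_corr(rr1, rc1)
        V[n:, n:] = g22 * S + s2u * I + s22 * self._resid_corr(rr2, rc2)
        b12 = g12 * S + s2u * I
        V[:n, n:] = b12
        V[n:, :n] = b12
        return V

    def loglik_G(self, th: np.ndarray) -> float:
        try:
            return reml_loglik_dense(self.y, self.X, self.covariance_from_G(th))
        except np.linalg.LinAlgError:
            return -np.inf

    @staticmethod
    def chol_to_G(th: np.ndarray) -> np.ndarray:
        """Map (l11, l21, l22, rest...) to (G11, G12, G22, rest...)."""
        l11, l21, l22 = th[:3]
        return np.concatenate([[l11 * l11, l11 * l21, l21 * l21 + l22 * l22], th[3:]])

    def loglik_chol(self, th: np.ndarray) -> float:
        return self.loglik_G(self.chol_to_G(th))

    def fit(self, starts: Sequence[np.ndarray], bounds,
            fixed: dict[int, float] | None = None,
            maxiter: int = 300) -> tuple[np.ndarray, float, bool]:
        """Bounded L-BFGS-B over the Cholesky parameterization.

        ``fixed`` pins parameters (by index in the theta vector) at given
        values; the remaining parameters are optimized.
        """
        k = len(starts[0])
        mask = np.ones(k, dtype=bool)
        template = np.zeros(k)
        for i, v in (fixed or {}).items():
            mask[i] = False
            template[i] = v

        def objective(th_free):
            th = template.copy()
            th[mask] = th_free
            val = self.loglik_chol(th)
            return 1e12 if not np.isfinite(val) else -val

        b = [bd for bd, m in zip(bounds, mask) if m]
        best = None
        converged = False
        for s in starts:
            s = np.asarray(s, dtype=float)[mask]
            res = optimize.minimize(objective, s, method="L-BFGS-B", bounds=b,
                                    options={"maxiter": maxiter, "ftol": 1e-11})
            if best is None or res.fun < best.fun:
                best = res
                converged = bool(res.success) or converged
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("bivariate REML optimization failed", last_iterate=best)
        th = template.copy()
        th[mask] = best.x
        return th, -best.fun, converged

    # -- uncertainty ----------------------------------------------------------
    _theta_G: np.ndarray | None = None

    def vcov_G_std(self) -> np.ndarray:
        """3x3 covariance of (G11, G12, G22) on the standardized scale."""
        th0 = np.asarray(self._theta_G, dtype=float).copy()
        k = th0.size
        scale = np.maximum(np.abs(th0), 1e-3)
        # keep variance-like parameters strictly positive while differencing
        var_idx = [0, 2, 3, 4] + ([7] if self.residual == "ar1xar1" else [5])
        for i in var_idx:
            th0[i] = max(th0[i], 1e-6)
        h = 1e-4 * scale
        f0 = self.loglik_G(th0)
        H = np.empty((k, k))
        for i in range(k):
            ei = np.zeros(k); ei[i] = h[i]
            H[i, i] = (self.loglik_G(th0 + ei) - 2 * f0 + self.loglik_G(th0 - ei)) / h[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    self.loglik_G(th0 + ei + ej) - self.loglik_G(th0 + ei - ej)
                    - self.loglik_G(th0 - ei + ej) + self.loglik_G(th0 - ei - ej)
                ) / (4 * h[i] * h[j])
        info = -H
        w, v = np.linalg.eigh((info + info.T) / 2.0)
        w = np.clip(w, 1e-10, None)
        cov = (v / w) @ v.T
        return cov[:3, :3]


# ---------------------------------------------------------------------------
# fitting


def _univariate_starts(stacked: StackedBivariate, residual: str):
    """Warm starts for (Gc chol, sigma2_u, per-trait residuals), standardized."""
    n = stacked.n_trees
    sub = stacked.layout
    spec = ModelSpec("x", residual=residual)
    out = []
    for k in range(2):
        v = stacked.y[k * n:(k + 1) * n]
        sd = np.std(v) or 1.0
        s = pd.Series(v / sd, index=sub.table["tree_id"])
        try:
            f = reml_fit(s, spec, sub, starts=((1.0, 0.3, 0.3),) if residual == "ar1xar1" else None)
            out.append(f)
        except Exception:
            out.append(None)
    g = []
    r = []
    for f in out:
        if f is None:
            g.append(0.3)
            r.append((0.7, 0.3, 0.3))
        else:
            g.append(max(f.sigma2_c, 0.01))
            r.append((max(f.sigma2, 0.05), f.rho_row or 0.0, f.rho_col or 0.0))
    # crude r_g start: correlation of clone means
    fr = stacked.frame
    m = fr.pivot_table(index="clone_id", columns="trait", values="value")
    r0 = 0.0
    if m.shape[0] >= 3 and m.notna().all(axis=None):
        with np.errstate(invalid="ignore"):
            cc = np.corrcoef(m.iloc[:, 0], m.iloc[:, 1])[0, 1]
        if np.isfinite(cc):
            r0 = float(np.clip(cc, -0.9, 0.9))
    return g, r, r0


def reml_fit_bivariate(
    stacked: StackedBivariate,
    residual: str = "ar1xar1",
    diag_gc: bool = False,
    extra_starts: int = 1,
    maxiter: int = 300,
) -> BivariateFit:
    """Fit the stacked bivariate model by REML.

    ``diag_gc=True`` pins the clonal covariance at zero (the reduced model of
    the r_g LRT). ``extra_starts`` adds a zero-correlation start beside the
    warm start built from the univariate fits.
    """
    prob = _BivariateProblem(stacked, residual=residual)
    g, r, r0 = _univariate_starts(stacked, residual)

    def start_vec(corr: float) -> np.ndarray:
        l11 = np.sqrt(g[0])
        l21 = corr * np.sqrt(g[1])
        l22 = np.sqrt(max(g[1] - l21**2, 1e-4))
        return np.array([l11, l21, l22, 0.05] + res_part)

    if residual == "ar1xar1":
        res_part = [r[0][0], r[0][1], r[0][2], r[1][0], r[1][1], r[1][2]]
        bounds = [(0.0, 10.0), (-10.0, 10.0), (0.0, 10.0), (0.0, 10.0),
                  (_MIN_RESID, 10.0), (-RHO_BOUND, RHO_BOUND), (-RHO_BOUND, RHO_BOUND),
                  (_MIN_RESID, 10.0), (-RHO_BOUND, RHO_BOUND), (-RHO_BOUND, RHO_BOUND)]
    else:
        res_part = [r[0][0], r[1][0]]
        bounds = [(0.0, 10.0), (-10.0, 10.0), (0.0, 10.0), (0.0, 10.0),
                  (_MIN_RESID, 10.0), (_MIN_RESID, 10.0)]
    fixed = {1: 0.0} if diag_gc else None
    starts = [start_vec(r0)]
    if extra_starts >= 1 and not diag_gc and abs(r0) > 1e-6:
        starts.append(start_vec(0.0))
    th, ll_std, converged = prob.fit(starts, bounds, fixed=fixed, maxiter=maxiter)

    # Degenerate or boundary solutions deserve a rescue pass: the Cholesky
    # parameterization has a zero-gradient saddle at Gc = 0, so a collapsed
    # clonal covariance can be an optimizer artifact. Stage A re-optimizes
    # Gc and the tree variance with the residual blocks frozen at their
    # univariate estimates (a well-conditioned 4-parameter subproblem) from
    # strongly correlated starts of both signs; stage B releases everything.
    if not diag_gc:
        thG_try = prob.chol_to_G(th)
        denom = np.sqrt(max(thG_try[0] * thG_try[2], 1e-12))
        collapsed = thG_try[0] < 1e-4 or thG_try[2] < 1e-4
        near_boundary = abs(thG_try[1]) / denom > 0.99
        if collapsed or near_boundary:
            freeze = {i: res_part[i - 4] for i in range(4, len(bounds))}
            for corr in (0.9, -0.9):
                th_a, _, _ = prob.fit([start_vec(corr)], bounds, fixed=freeze,
                                      maxiter=maxiter)
                th_b, ll_b, conv_b = prob.fit([th_a], bounds, maxiter=maxiter)
                if ll_b > ll_std:
                    th, ll_std, converged = th_b, ll_b, conv_b

    thG = prob.chol_to_G(th)
    prob._theta_G = thG
    d1, d2 = prob.scale
    Gc = np.array([[thG[0] * d1 * d1, thG[1] * d1 * d2],
                   [thG[1] * d1 * d2, thG[2] * d2 * d2]])
    if residual == "ar1xar1":
        resid1 = {"sigma2": thG[4] * d1 * d1, "rho_row": thG[5], "rho_col": thG[6]}
        resid2 = {"sigma2": thG[7] * d2 * d2, "rho_row": thG[8], "rho_col": thG[9]}
    else:
        resid1 = {"sigma2": thG[4] * d1 * d1}
        resid2 = {"sigma2": thG[5] * d2 * d2}
    # sigma2_u is a shared (cross-trait) variance; report on the geometric scale
    sigma2_u = float(thG[3] * d1 * d2)
    # restricted log-likelihood on the original response scale for comparability
    ll = _original_scale_loglik(stacked, prob, thG, residual)
    return BivariateFit(
        trait_names=stacked.trait_names,
        Gc=Gc,
        sigma2_u=sigma2_u,
        resid1=resid1,
        resid2=resid2,
        loglik=float(ll),
        converged=converged,
        n_records=stacked.n_records,
        residual=residual,
        _machinery=prob,
        _scale=prob.scale,
    )


def _original_scale_loglik(stacked, prob, thG, residual) -> float:
    d1, d2 = prob.scale
    n = stacked.n_trees
    D = np.concatenate([np.full(n, d1), np.full(n, d2)])
    Vstd = prob.covariance_from_G(thG)
    V = Vstd * np.outer(D, D)
    return reml_loglik_dense(stacked.y, stacked.X, V)


def genetic_correlation(fit: BivariateFit, p: float | None = None) -> GeneticCorrelation:
    """r_g = Gc12 / sqrt(Gc11 Gc22) with delta-method SE and boundary flag."""
    g11, g22 = fit.Gc[0, 0], fit.Gc[1, 1]
    g12 = fit.Gc[0, 1]
    d1, d2 = fit._scale if fit._scale is not None else (1.0, 1.0)
    if g11 <= _MIN_CLONAL_VAR * d1 * d1 or g22 <= _MIN_CLONAL_VAR * d2 * d2:
        raise UndefinedCorrelationError(
            "a clonal variance is numerically zero; genetic correlation undefined"
        )
    r = g12 / np.sqrt(g11 * g22)
    if abs(r) > BOUNDARY_RG:
        return GeneticCorrelation(r_g=float(np.sign(r) * BOUNDARY_RG), se=None,
                                  boundary=True, p=p)
    grad = np.array([-r / (2 * g11), 1.0 / np.sqrt(g11 * g22), -r / (2 * g22)])
    V = fit.vcov_G()
    se = float(np.sqrt(max(0.0, grad @ V @ grad)))
    return GeneticCorrelation(r_g=float(r), se=se, boundary=False, p=p)


def genetic_correlation_with_test(
    stacked: StackedBivariate,
    residual: str = "ar1xar1",
    maxiter: int = 300,
) -> tuple[BivariateFit, GeneticCorrelation]:
    """Full fit plus the 1-df LRT of Gc12 = 0 (interior null, plain chi2)."""
    full = reml_fit_bivariate(stacked, residual=residual, maxiter=maxiter)
    red = reml_fit_bivariate(stacked, residual=residual, diag_gc=True, maxiter=maxiter)
    stat = max(0.0, 2.0 * (full.loglik - red.loglik))
    p = 1.0 if stat == 0.0 else float(stats.chi2.sf(stat, 1))
    return full, genetic_correlation(full, p=p)
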