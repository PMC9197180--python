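"""Univariate spatial REML: design pieces, likelihood, tests, heritability."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import null_space
from scipy.stats import multivariate_normal

from clonalspec import lmm_spatial as lmm
from clonalspec import synth_trial as st
from conftest import simulate_trait


def restricted_loglik_bruteforce(y, X, V):
    """Independent oracle: project onto an orthonormal basis of the error
    contrasts and evaluate the Gaussian log-density directly."""
    K = null_space(np.asarray(X, dtype=float).T)
    z = K.T @ np.asarray(y, dtype=float)
    return multivariate_normal.logpdf(z, mean=np.zeros(K.shape[1]), cov=K.T @ V @ K)


class TestOrthogonalPolynomials:
    def test_columns_orthonormal(self):
        B = lmm.orthogonal_polynomial_basis(np.arange(1, 13), degree=2)
        G = B.T @ B
        np.testing.assert_allclose(G, np.eye(2), atol=1e-10)
        assert abs(B.sum(axis=0)).max() < 1e-10  # orthogonal to the constant

    def test_constant_indices_rejected(self):
        with pytest.raises(lmm.RankError):
            lmm.orthogonal_polynomial_basis(np.full(10, 3.0), degree=2)

    def test_spans_centered_quadratic(self):
        x = np.arange(1, 21, dtype=float)
        B = lmm.orthogonal_polynomial_basis(x, degree=2)
        target = (x - x.mean()) ** 2
        target = target - target.mean()
        resid = target - B @ (B.T @ target)
        assert np.linalg.norm(resid) < 1e-10


class TestAR1Correlation:
    def test_zero_rho_identity(self):
        np.testing.assert_allclose(lmm.ar1_correlation(0.0, [1, 2, 3]), np.eye(3))

    def test_explicit_values(self):
        C = lmm.ar1_correlation(0.5, [1, 2, 3])
        expect = np.array([[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]])
        np.testing.assert_allclose(C, expect, atol=1e-15)

    def test_positive_definite_near_unit_rho(self):
        C = lmm.ar1_correlation(0.95, np.arange(50))
        assert np.linalg.eigvalsh(C).min() > 0

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            lmm.ar1_correlation(1.0, [1, 2])


class TestResidualCovariance:
    @staticmethod
    def _grid_layout(nr, nc, drop=()):
        recs = [
            {"row": r, "col": c, "tree_id": f"T{r}_{c}", "clone_id": f"C{(r + c) % 3}",
             "ecotype": "low"}
            for r in range(1, nr + 1) for c in range(1, nc + 1)
            if (r, c) not in drop
        ]
        return st.TrialLayout(pd.DataFrame(recs))

    def test_zero_rho_gives_scaled_identity(self):
        lay = self._grid_layout(3, 3)
        R = lmm.residual_covariance({"sigma2": 2.5, "rho_row": 0.0, "rho_col": 0.0}, lay)
        np.testing.assert_allclose(R, 2.5 * np.eye(9), atol=1e-15)

    def test_full_grid_matches_kronecker(self):
        lay = self._grid_layout(3, 3)
        R = lmm.residual_covariance({"sigma2": 1.7, "rho_row": 0.4, "rho_col": -0.3}, lay)
        Ar = lmm.ar1_correlation(0.4, [1, 2, 3])
        Ac = lmm.ar1_correlation(-0.3, [1, 2, 3])
        # layout is sorted by (row, col): row index varies slowest
        expect = 1.7 * np.kron(Ar, Ac)
        np.testing.assert_allclose(R, expect, atol=1e-12)

    def test_holey_grid_is_submatrix(self):
        full = self._grid_layout(3, 3)
        holey = self._grid_layout(3, 3, drop=((2, 2),))
        params = {"sigma2": 1.0, "rho_row": 0.6, "rho_col": 0.5}
        Rf = lmm.residual_covariance(params, full)
        Rh = lmm.residual_covariance(params, holey)
        keep = [i for i, t in enumerate(full.table["tree_id"]) if t != "T2_2"]
        np.testing.assert_allclose(Rh, Rf[np.ix_(keep, keep)], atol=1e-15)

    def test_unknown_structure(self):
        lay = self._grid_layout(2, 2)
        with pytest.raises(ValueError, match="unknown residual structure"):
            lmm.residual_covariance({"sigma2": 1.0}, lay, structure="toeplitz")


class TestRemlLoglik:
    def test_matches_bruteforce_on_tiny_instance(self):
        lay = st.simulate_layout(4, 5, 6, 3, seed=2)
        y = simulate_trait(lay, 0.5, 1.0, 0.3, 0.2, seed=7)
        spec = lmm.ModelSpec("y")
        X, _ = lmm.build_design(lay, spec)
        yv = y.reindex(lay.table["tree_id"]).to_numpy()
        prob = lmm._REMLProblem(yv, X, lay, spec)
        for pars in (
            {"sigma2_c": 0.4, "sigma2": 0.6, "rho_row": 0.5, "rho_col": 0.5},
            {"sigma2_c": 0.0, "sigma2": 1.0, "rho_row": 0.0, "rho_col": 0.0},
            {"sigma2_c": 2.0, "sigma2": 0.3, "rho_row": -0.7, "rho_col": 0.9},
        ):
            V = lmm.residual_covariance(pars, lay) + pars["sigma2_c"] * prob.same_clone
            assert prob.reml_loglik(pars) == pytest.approx(
                restricted_loglik_bruteforce(yv, X, V), abs=1e-6
            )

    def test_fit_optimum_consistent_with_loglik(self, small_layout):
        y = simulate_trait(small_layout, 0.4, 0.6, 0.5, 0.5, seed=3)
        fit = lmm.reml_fit(y, lmm.ModelSpec("y"), small_layout)
        pars = dict(zip(fit.varpar_names, fit.varpar_values()))
        assert fit._problem.reml_loglik(pars) == pytest.approx(fit.loglik, abs=1e-6)

    def test_monotone_optimizer_trace(self, small_layout):
        y = simulate_trait(small_layout, 0.4, 0.6, 0.5, 0.5, seed=4)
        fit = lmm.reml_fit(y, lmm.ModelSpec("y"), small_layout)
        assert all(b >= a for a, b in zip(fit.trace, fit.trace[1:]))

    def test_relabeling_invariance(self, small_layout):
        # shifting all row/col indices preserves lags, hence the fit
        y = simulate_trait(small_layout, 0.4, 0.6, 0.5, 0.5, seed=5)
        shifted = st.TrialLayout(small_layout.table.assign(
            row=small_layout.table["row"] + 7, col=small_layout.table["col"] + 3))
        f1 = lmm.reml_fit(y, lmm.ModelSpec("y"), small_layout)
        f2 = lmm.reml_fit(y, lmm.ModelSpec("y"), shifted)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
        assert f1.sigma2_c == pytest.approx(f2.sigma2_c, abs=1e-6)

    def test_missing_responses_dropped_listwise(self, small_layout):
        y = simulate_trait(small_layout, 0.4, 0.6, 0.3, 0.3, seed=6)
        y_missing = y.copy()
        y_missing.iloc[:4] = np.nan
        fit = lmm.reml_fit(y_missing, lmm.ModelSpec("y"), small_layout)
        assert fit.n_obs == len(y) - 4

    def test_null_clone_variance_recovery(self, recovery_layout):
        # data without clone structure: the clone-variance estimate stays at
        # the boundary-bias level (the mean of the positive part of its
        # sampling distribution, ~0.05 sigma2 for 30 clones), not above it
        est = []
        for s in range(150):
            y = simulate_trait(recovery_layout, 0.0, 1.0, 0.0, 0.0, seed=200 + s)
            fit = lmm.reml_fit(y, lmm.ModelSpec("y", residual="iid"), recovery_layout)
            est.append(fit.sigma2_c / fit.sigma2)
        assert np.mean(est) <= 0.08


class TestLikelihoodRatio:
    def test_identical_fits_give_unity_p(self, small_layout):
        y = simulate_trait(small_layout, 0.4, 0.6, 0.0, 0.0, seed=8)
        fit = lmm.reml_fit(y, lmm.ModelSpec("y", residual="iid"), small_layout)
        res = lmm.likelihood_ratio_test(fit, fit, boundary=True, df=1)
        assert res.statistic == 0.0 and res.p == 1.0
        res2 = lmm.likelihood_ratio_test(fit, fit, boundary=False, df=2)
        assert res2.p == 1.0

    def test_chi2_tail_value(self, small_layout):
        y = simulate_trait(small_layout, 0.8, 0.4, 0.0, 0.0, seed=9)
        full = lmm.reml_fit(y, lmm.ModelSpec("y", residual="iid"), small_layout)
        fake_reduced = lmm.reml_fit(y, lmm.ModelSpec("y", residual="iid", clone_effect=False),
                                    small_layout)
        # check the mapping statistic -> p against the chi-square tail
        res = lmm.likelihood_ratio_test(full, fake_reduced, boundary=False, df=1)
        from scipy.stats import chi2
        assert res.p == pytest.approx(chi2.sf(res.statistic, 1), abs=1e-12)

    def test_incomparable_fixed_parts_rejected(self, small_layout):
        y = simulate_trait(small_layout, 0.4, 0.6, 0.0, 0.0, seed=10)
        f1 = lmm.reml_fit(y, lmm.ModelSpec("y", residual="iid"), small_layout)
        f2 = lmm.reml_fit(y, lmm.ModelSpec("y", residual="iid", row_poly=False), small_layout)
        with pytest.raises(lmm.ComparabilityError):
            lmm.likelihood_ratio_test(f1, f2)


class TestWaldF:
    def test_single_coefficient_equals_t_squared(self, small_layout):
        y = simulate_trait(small_layout, 0.3, 0.7, 0.0, 0.0, seed=11)
        fit = lmm.reml_fit(y, lmm.ModelSpec("y", residual="iid"), small_layout)
        res = lmm.wald_f_test(fit, "intercept")
        b = fit.beta[fit.fixed_terms["intercept"]][0]
        se = np.sqrt(fit._beta_cov[fit.fixed_terms["intercept"], fit.fixed_terms["intercept"]][0, 0])
        assert res.f == pytest.approx((b / se) ** 2, rel=1e-10)
        assert res.df1 == 1 and res.df2 == fit.n_obs - fit.n_fixed

    def test_absent_term_rejected(self, small_layout):
        y = simulate_trait(small_layout, 0.3, 0.7, 0.0, 0.0, seed=12)
        fit = lmm.reml_fit(y, lmm.ModelSpec("y", residual="iid", row_poly=False), small_layout)
        with pytest.raises(KeyError):
            lmm.wald_f_test(fit, "row_poly")

    def test_null_effect_rejection_rate(self, small_layout):
        # the row polynomial has no true effect; rejection should sit near alpha
        rej = 0
        n = 150
        for s in range(n):
            y = simulate_trait(small_layout, 0.0, 1.0, 0.0, 0.0, seed=3000 + s,
                               trend=(0.0, 0.0, 0.0, 0.0))
            fit = lmm.reml_fit(y, lmm.ModelSpec("y", residual="iid", clone_effect=False),
                               small_layout)
            rej += lmm.wald_f_test(fit, "row_poly").p < 0.05
        assert abs(rej / n - 0.05) < 0.05


class TestHeritability:
    @staticmethod
    def _fit_with(sigma2_c, sigma2, vcov):
        fit = lmm.UnivariateFit(
            spec=lmm.ModelSpec("y", residual="iid"), sigma2_c=sigma2_c, sigma2=sigma2,
            rho_row=None, rho_col=None, beta=np.array([0.0]),
            fixed_terms={"intercept": slice(0, 1)}, loglik=0.0, converged=True,
            n_obs=10, n_fixed=1, varpar_names=("sigma2_c", "sigma2"),
        )
        fit._vcov = np.asarray(vcov, dtype=float)
        return fit

    def test_equal_components_give_half(self):
        est = lmm.heritability(self._fit_with(2.0, 2.0, np.eye(2) * 0.1))
        assert est.h2 == pytest.approx(0.5)

    def test_zero_clone_variance_gives_zero(self):
        est = lmm.heritability(self._fit_with(0.0, 1.0, np.eye(2) * 0.1))
        assert est.h2 == 0.0

    def test_delta_method_spot_value(self):
        est = lmm.heritability(self._fit_with(1.0, 1.0, np.diag([0.1, 0.1])))
        assert est.se == pytest.approx(np.sqrt(0.25**2 * 0.1 + 0.25**2 * 0.1), abs=1e-12)
        assert est.se == pytest.approx(0.1118, abs=5e-4)

    def test_zero_total_variance_undefined(self):
        with pytest.raises(ZeroDivisionError):
            lmm.heritability(self._fit_with(0.0, 0.0, np.eye(2)))
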