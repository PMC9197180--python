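"""Generator contracts: layouts, genetic values, spatial fields, spectra."""

import numpy as np
import pandas as pd
import pytest

from clonalspec import synth_trial as st
from clonalspec.spectra import DEFAULT_GRID


class TestLayout:
    def test_forced_single_clone(self):
        lay = st.simulate_layout(1, 3, 1, 3, seed=0)
        assert lay.n_trees == 3
        assert lay.table["clone_id"].nunique() == 1

    def test_deterministic_for_seed(self):
        a = st.simulate_layout(8, 8, 10, 3, seed=42)
        b = st.simulate_layout(8, 8, 10, 3, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_counts_on_reference_design(self):
        lay = st.simulate_layout(10, 10, 30, 3, seed=1)
        assert lay.n_trees == 90
        assert (lay.clone_counts() == 3).all()
        assert not lay.table.duplicated(["row", "col"]).any()

    def test_capacity_error(self):
        with pytest.raises(st.SizingError):
            st.simulate_layout(3, 3, 5, 2, seed=0)

    def test_ecotype_constant_within_clone(self):
        lay = st.simulate_layout(10, 10, 20, 4, seed=3)
        assert (lay.table.groupby("clone_id")["ecotype"].nunique() == 1).all()

    def test_clonal_rows_contiguous(self):
        lay = st.simulate_layout(6, 6, 6, 3, seed=5, clonal_rows=True)
        # ramets of one clone sit at consecutive row-major positions
        t = lay.table.sort_values(["row", "col"]).reset_index(drop=True)
        runs = t["clone_id"].ne(t["clone_id"].shift()).cumsum().value_counts()
        assert (runs == 3).all()

    def test_csv_round_trip(self, tmp_path, small_layout):
        p = tmp_path / "layout.csv"
        small_layout.to_csv(p)
        back = st.TrialLayout.from_csv(p)
        pd.testing.assert_frame_equal(
            back.table, small_layout.table[back.table.columns]
        )


class TestGeneticValues:
    def test_zero_covariance_gives_zero_values(self):
        gv = st.simulate_genetic_values(["c1", "c2"], np.zeros((2, 2)), seed=0)
        assert (gv.to_numpy() == 0).all()

    def test_independent_traits_uncorrelated(self):
        ids = [f"c{i}" for i in range(10_000)]
        gv = st.simulate_genetic_values(ids, np.eye(2), seed=1)
        r = np.corrcoef(gv.iloc[:, 0], gv.iloc[:, 1])[0, 1]
        assert abs(r) < 0.03

    def test_correlated_traits_recover_correlation(self):
        ids = [f"c{i}" for i in range(10_000)]
        G = np.array([[1.0, 0.8], [0.8, 1.0]])
        gv = st.simulate_genetic_values(ids, G, seed=2)
        r = np.corrcoef(gv.iloc[:, 0], gv.iloc[:, 1])[0, 1]
        assert abs(r - 0.8) < 0.02

    def test_non_psd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            st.simulate_genetic_values(["c1"], bad, seed=0)


class TestSpatialSurface:
    @staticmethod
    def _full_grid(nr, nc):
        table = pd.DataFrame(
            [
                {"row": r, "col": c, "tree_id": f"T{r}_{c}", "clone_id": "C1",
                 "ecotype": "low"}
                for r in range(1, nr + 1) for c in range(1, nc + 1)
            ]
        )
        return st.TrialLayout(table)

    def _row_lag1(self, lay, rho_row, rho_col, sigma2, n_fields, seed0):
        nr = lay.table["row"].max()
        nc = lay.table["col"].max()
        acc = []
        var = []
        for s in range(n_fields):
            surf = st.simulate_spatial_surface(lay, rho_row, rho_col, sigma2, seed=seed0 + s)
            f = surf.to_numpy().reshape(nr, nc)
            acc.append(np.corrcoef(f[:-1].ravel(), f[1:].ravel())[0, 1])
            var.append(f.var(ddof=1))
        return np.mean(acc), np.mean(var)

    def test_independent_noise_has_no_lag_correlation(self):
        lay = self._full_grid(20, 20)
        lag1, _ = self._row_lag1(lay, 0.0, 0.0, 1.0, 50, 100)
        assert abs(lag1) < 3 / np.sqrt(50 * 380)

    def test_row_autocorrelation_recovered(self):
        lay = self._full_grid(20, 20)
        lag1, _ = self._row_lag1(lay, 0.6, 0.0, 1.0, 200, 500)
        assert abs(lag1 - 0.6) < 0.03

    def test_marginal_variance_recovered(self):
        lay = self._full_grid(20, 20)
        _, var = self._row_lag1(lay, 0.3, 0.3, 4.0, 200, 900)
        assert abs(var - 4.0) / 4.0 < 0.05

    def test_invalid_rho_rejected(self, small_layout):
        with pytest.raises(ValueError, match="rho_row"):
            st.simulate_spatial_surface(small_layout, 1.0, 0.0, 1.0, seed=0)

    def test_trend_only_is_deterministic_polynomial(self, small_layout):
        surf = st.simulate_spatial_surface(small_layout, 0.0, 0.0, 0.0,
                                           trend_coeffs=(1.0, 0.5, -0.3, 0.2), seed=0)
        expect = st.spatial_trend(small_layout, (1.0, 0.5, -0.3, 0.2))
        np.testing.assert_allclose(surf.to_numpy(), expect, atol=1e-12)


class TestTraits:
    def test_zero_variance_gives_means(self, small_layout):
        clones = sorted(small_layout.table["clone_id"].unique())
        gv = st.simulate_genetic_values(clones, np.zeros((1, 1)), seed=0,
                                        trait_names=["y"])
        surf = st.simulate_spatial_surface(small_layout, 0.0, 0.0, 0.0, seed=0)
        tt = st.simulate_traits(small_layout, gv, {"y": surf}, {"y": 7.5})
        assert (tt.data["y"] == 7.5).all()

    def test_generative_heritability_formula(self):
        truth = st.default_truth(h2={t: 0.4 for t in st.default_truth().trait_names})
        for t in truth.trait_names:
            s2c = truth.genetic_covariance()[truth.trait_names.index(t)][truth.trait_names.index(t)]
            s2 = truth.residual_variance(t)
            assert abs(s2c / (s2c + s2) - 0.4) < 1e-12

    def test_clone_variance_recovered_method_of_moments(self, small_layout):
        # one-way ANOVA on clone means over replicate datasets
        clones = sorted(small_layout.table["clone_id"].unique())
        k = len(clones)
        est = []
        for s in range(500):
            gv = st.simulate_genetic_values(clones, np.array([[0.4]]), seed=s,
                                            trait_names=["y"])
            surf = st.simulate_spatial_surface(small_layout, 0.0, 0.0, 0.6, seed=s + 10_000)
            tt = st.simulate_traits(small_layout, gv, {"y": surf}, {"y": 0.0})
            df = pd.DataFrame({
                "y": tt.data["y"].to_numpy(),
                "clone": small_layout.table["clone_id"].to_numpy(),
            })
            means = df.groupby("clone")["y"].mean()
            within = df.groupby("clone")["y"].var(ddof=1).mean()
            est.append(means.var(ddof=1) - within / 3)
        mc_se = np.std(est) / np.sqrt(len(est))
        assert abs(np.mean(est) - 0.4) < 3 * mc_se + 0.01

    def test_dimension_mismatch_rejected(self, small_layout):
        clones = sorted(small_layout.table["clone_id"].unique())
        gv = st.simulate_genetic_values(clones, np.eye(2), seed=0,
                                        trait_names=["y", "z"])
        surf = st.simulate_spatial_surface(small_layout, 0.0, 0.0, 1.0, seed=0)
        with pytest.raises(ValueError, match="one spatial surface per trait"):
            st.simulate_traits(small_layout, gv, {"y": surf}, {"y": 0.0})


def _trait_table_for_spectra(chl_a, water=0.0, structure=0.0, n=1):
    idx = [f"T{i}" for i in range(n)]
    data = pd.DataFrame(
        {
            "chl_a": np.full(n, chl_a) if np.isscalar(chl_a) else chl_a,
            "chl_b": np.zeros(n),
            "water": np.full(n, water) if np.isscalar(water) else water,
            "structure": np.full(n, structure) if np.isscalar(structure) else structure,
        },
        index=pd.Index(idx, name="tree_id"),
    )
    return st.TraitTable(data)


class TestSpectra:
    def test_chlorophyll_deepens_red_absorption(self):
        tt = _trait_table_for_spectra(chl_a=np.array([2.0, 4.0]), n=2)
        spec = st.simulate_spectra(tt, noise_sd=0.0, seed=0)
        r680 = spec.reflectance(680)
        r550 = spec.reflectance(550)
        assert r680.iloc[1] < r680.iloc[0]
        assert r550.iloc[1] < r550.iloc[0]

    def test_water_and_structure_monotonicity(self):
        tt = _trait_table_for_spectra(chl_a=3.0, water=np.array([-1.0, 1.0]), n=2)
        spec = st.simulate_spectra(tt, noise_sd=0.0, seed=0)
        for band in (970, 1200, 1450, 1930):
            assert spec.reflectance(band).iloc[1] < spec.reflectance(band).iloc[0]
        tt = _trait_table_for_spectra(chl_a=3.0, structure=np.array([-1.0, 1.0]), n=2)
        spec = st.simulate_spectra(tt, noise_sd=0.0, seed=0)
        for band in (800, 1000, 1250):
            assert spec.reflectance(band).iloc[1] > spec.reflectance(band).iloc[0]

    def test_zero_links_reproduce_baseline(self):
        tt = _trait_table_for_spectra(chl_a=5.0, water=2.0, structure=-1.0, n=3)
        link = st.SpectralLink(pigment_vis=0.0, water_swir=0.0, structure_nir=0.0)
        spec = st.simulate_spectra(tt, link=link, noise_sd=0.0, seed=0)
        base = st.baseline_reflectance(DEFAULT_GRID)
        np.testing.assert_allclose(spec.values.to_numpy(),
                                   np.tile(base, (3, 1)), atol=1e-12)

    def test_regression_recovers_pigment_link(self):
        rng = np.random.default_rng(3)
        chl = rng.uniform(2.0, 6.0, size=1000)
        tt = _trait_table_for_spectra(chl_a=chl, n=1000)
        spec = st.simulate_spectra(tt, noise_sd=0.001, seed=4)
        slope = np.polyfit(chl, spec.reflectance(680).to_numpy(), 1)[0]
        assert abs(-slope - st.SpectralLink().pigment_vis) / st.SpectralLink().pigment_vis < 0.05

    def test_bounded_and_deterministic(self):
        tt = _trait_table_for_spectra(chl_a=np.array([0.0, 30.0, 5.0]), n=3)
        a = st.simulate_spectra(tt, noise_sd=0.01, seed=9)
        b = st.simulate_spectra(tt, noise_sd=0.01, seed=9)
        assert (a.values.to_numpy() >= 0).all() and (a.values.to_numpy() <= 1).all()
        pd.testing.assert_frame_equal(a.values, b.values)


def test_dataset_determinism():
    t = st.default_truth(seed=5)
    a = st.simulate_dataset(t)
    b = st.simulate_dataset(t)
    pd.testing.assert_frame_equal(a.traits.data, b.traits.data)
    pd.testing.assert_frame_equal(a.spectra.values, b.spectra.values)
    pd.testing.assert_frame_equal(a.layout.table, b.layout.table)
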