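"""Shared fixtures: small trial layouts and simulated datasets."""

import numpy as np
import pandas as pd
import pytest

from clonalspec import synth_trial as st


@pytest.fixture(scope="session")
def small_layout():
    """6x6 grid, 12 clones x 3 ramets (36 trees)."""
    return st.simulate_layout(6, 6, 12, 3, seed=11)


@pytest.fixture(scope="session")
def recovery_layout():
    """10x10 grid, 30 clones x 3 ramets (90 trees): the reference design."""
    return st.simulate_layout(10, 10, 30, 3, seed=1)


def simulate_trait(layout, sigma2_c, sigma2, rho_row, rho_col, seed,
                   trend=(0.2, -0.1, 0.15, 0.1), mean=10.0, name="y"):
    """One trait on a layout with known variance components."""
    clones = sorted(layout.table["clone_id"].unique())
    gv = st.simulate_genetic_values(clones, np.array([[sigma2_c]]), seed=seed,
                                    trait_names=[name])
    surf = st.simulate_spatial_surface(layout, rho_row, rho_col, sigma2,
                                       trend_coeffs=trend, seed=seed + 100_000)
    tt = st.simulate_traits(layout, gv, {name: surf}, {name: mean})
    return tt.data[name]


def simulate_trait_pair(layout, G, sigma2, rho, seed, means=(5.0, 2.0)):
    """Two traits with genetic covariance G and independent spatial noise."""
    clones = sorted(layout.table["clone_id"].unique())
    gv = st.simulate_genetic_values(clones, np.asarray(G, dtype=float),
                                    seed=seed, trait_names=["a", "b"])
    sa = st.simulate_spatial_surface(layout, rho, rho, sigma2,
                                     (0.2, -0.1, 0.15, 0.1), seed=seed + 50_000)
    sb = st.simulate_spatial_surface(layout, rho, rho, sigma2,
                                     (0.1, 0.1, -0.1, 0.05), seed=seed + 90_000)
    tt = st.simulate_traits(layout, gv, {"a": sa, "b": sb},
                            {"a": means[0], "b": means[1]})
    return tt.data["a"], tt.data["b"]


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic trial from the default truth parameters."""
    return st.simulate_dataset(st.default_truth(seed=7))
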