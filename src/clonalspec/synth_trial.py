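"""Synthetic clonal field-trial generator with known ground truth.

Emulates the data-generating process of a replicated clonal conifer trial:

* a row x column planting grid with clones replicated as ramets (optionally
  as contiguous clonal rows) and clone-level ecotype labels;
* clone genetic values drawn from a multivariate normal with genetic
  covariance ``G`` across traits;
* a smooth second-order spatial trend plus separable AR1xAR1 microsite noise
  per trait (correlation decaying geometrically with row lag and column lag);
* per-tree trait values = trait mean (+ optional ecotype shift) + genetic
  value + spatial surface;
* shoot reflectance spectra built from a vegetation-like baseline curve with
  Gaussian absorption features tied to traits: chlorophyll deepens the
  550/680-nm absorptions, a latent water variable deepens the
  970/1200/1450/1930-nm bands, and a latent structure variable raises the
  NIR plateau (760-1300 nm).

Everything is deterministic for a fixed seed, so downstream estimators can be
validated against the exact generative truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra import DEFAULT_GRID, SpectraMatrix

ECOTYPES = ("low", "medium", "high")


class SizingError(ValueError):
    """Grid capacity cannot hold the requested clones x ramets."""


# ---------------------------------------------------------------------------
# layout


@dataclass(frozen=True)
class TrialLayout:
    """Field positions of the trial's trees.

    ``table`` has columns ``row, col, tree_id, clone_id, ecotype`` with one
    record per occupied position; (row, col) pairs are unique, every clone
    appears at least once, and ecotype is constant within a clone.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"row", "col", "tree_id", "clone_id", "ecotype"}
        if missing := required - set(t.columns):
            raise ValueError(f"layout table missing columns {sorted(missing)}")
        if t.duplicated(["row", "col"]).any():
            raise ValueError("duplicate (row, col) positions in layout")
        if t["tree_id"].duplicated().any():
            raise ValueError("duplicate tree ids in layout")
        if (t["row"] < 1).any() or (t["col"] < 1).any():
            raise ValueError("grid coordinates are 1-based integers")
        if (t.groupby("clone_id")["ecotype"].nunique() > 1).any():
            raise ValueError("ecotype must be constant within a clone")

    @property
    def n_trees(self) -> int:
        return len(self.table)

    @property
    def tree_ids(self) -> pd.Index:
        return pd.Index(self.table["tree_id"])

    def clone_counts(self) -> pd.Series:
        return self.table["clone_id"].value_counts()

    def subset(self, tree_ids: Sequence) -> "TrialLayout":
        keep = self.table[self.table["tree_id"].isin(tree_ids)].reset_index(drop=True)
        return TrialLayout(keep)

    def to_csv(self, path) -> None:
        self.table[["row", "col", "tree_id", "clone_id", "ecotype"]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialLayout":
        return cls(pd.read_csv(path))


def simulate_layout(
    n_rows: int,
    n_cols: int,
    n_clones: int,
    ramets_per_clone: int,
    ecotype_fractions: Mapping[str, float] | None = None,
    seed: int = 0,
    clonal_rows: bool = False,
) -> TrialLayout:
    """Assign replicated clones to a planting grid.

    With ``clonal_rows=True`` the ramets of each clone occupy consecutive
    positions along a row (clonal-row planting); otherwise positions are
    fully randomized. Unused grid positions stay empty (missing positions).
    """
    n_trees = n_clones * ramets_per_clone
    if n_rows * n_cols < n_trees:
        raise SizingError(
            f"grid {n_rows}x{n_cols} cannot hold {n_clones} clones x {ramets_per_clone} ramets"
        )
    rng = np.random.default_rng(seed)
    if ecotype_fractions is None:
        ecotype_fractions = {e: 1.0 / len(ECOTYPES) for e in ECOTYPES}
    probs = np.array([ecotype_fractions.get(e, 0.0) for e in ECOTYPES], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("ecotype fractions must sum to a positive value")
    probs = probs / probs.sum()
    clone_ecotype = rng.choice(len(ECOTYPES), size=n_clones, p=probs)

    positions = [(r, c) for r in range(1, n_rows + 1) for c in range(1, n_cols + 1)]
    if clonal_rows:
        # fill row-major, one clone's ramets contiguous; clone order randomized
        order = rng.permutation(n_clones)
        chosen = positions[:n_trees]
        clone_of = np.repeat(order, ramets_per_clone)
    else:
        idx = rng.choice(len(positions), size=n_trees, replace=False)
        chosen = [positions[i] for i in idx]
        clone_of = rng.permutation(np.repeat(np.arange(n_clones), ramets_per_clone))

    table = pd.DataFrame(
        {
            "row": [p[0] for p in chosen],
            "col": [p[1] for p in chosen],
            "tree_id": [f"T{i + 1:04d}" for i in range(n_trees)],
            "clone_id": [f"C{c + 1:03d}" for c in clone_of],
            "ecotype": [ECOTYPES[clone_ecotype[c]] for c in clone_of],
        }
    ).sort_values(["row", "col"], ignore_index=True)
    return TrialLayout(table)


# ---------------------------------------------------------------------------
# genetic values


def _validate_covariance(G: np.ndarray) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("G must be a square matrix")
    if not np.allclose(G, G.T, atol=1e-10):
        raise ValueError("G must be symmetric")
    w = np.linalg.eigvalsh(G)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("G must be positive semi-definite")
    return G


def simulate_genetic_values(
    clone_ids: Sequence[str],
    G: np.ndarray,
    seed: int = 0,
    trait_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Clone x trait matrix of genetic values, rows iid MVN(0, G)."""
    G = _validate_covariance(G)
    k = G.shape[0]
    if trait_names is None:
        trait_names = [f"trait{i + 1}" for i in range(k)]
    if len(trait_names) != k:
        raise ValueError("trait_names length must match G")
    rng = np.random.default_rng(seed)
    # eigendecomposition square root: exact for singular G (e.g. G = 0)
    w, v = np.linalg.eigh(G)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((len(clone_ids), k))
    return pd.DataFrame(z @ root.T, index=pd.Index(clone_ids, name="clone_id"), columns=list(trait_names))


# ---------------------------------------------------------------------------
# spatial surface


def _check_rho(rho: float, name: str) -> None:
    if not abs(rho) < 1:
        raise ValueError(f"|{name}| must be < 1, got {rho}")


def _normalized_index(i: np.ndarray) -> np.ndarray:
    """Map 1-based grid indices onto [-1, 1] (constant axis maps to 0)."""
    i = np.asarray(i, dtype=float)
    lo, hi = i.min(), i.max()
    if hi == lo:
        return np.zeros_like(i)
    return 2.0 * (i - lo) / (hi - lo) - 1.0


def spatial_trend(layout: TrialLayout, trend_coeffs: Sequence[float]) -> np.ndarray:
    """Second-order polynomial trend over the grid.

    ``trend_coeffs = (row_lin, row_quad, col_lin, col_quad)`` in trait units,
    applied to row/col indices normalized to [-1, 1].
    """
    a1, a2, b1, b2 = trend_coeffs
    zr = _normalized_index(layout.table["row"].to_numpy())
    zc = _normalized_index(layout.table["col"].to_numpy())
    return a1 * zr + a2 * zr**2 + b1 * zc + b2 * zc**2


def simulate_spatial_surface(
    layout: TrialLayout,
    rho_row: float,
    rho_col: float,
    sigma2: float,
    trend_coeffs: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
    seed: int = 0,
) -> pd.Series:
    """Trend plus AR1xAR1 noise at each occupied position.

    The noise covariance between positions (r1,c1) and (r2,c2) is
    ``sigma2 * rho_row**|r1-r2| * rho_col**|c1-c2|`` — the observed-position
    submatrix of the full-grid separable process. Sampling uses the
    matrix-normal identity E = L_row N L_col' on the full grid.
    """
    _check_rho(rho_row, "rho_row")
    _check_rho(rho_col, "rho_col")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    rows = layout.table["row"].to_numpy()
    cols = layout.table["col"].to_numpy()
    nr, nc = rows.max(), cols.max()
    lr = np.linalg.cholesky(rho_row ** np.abs(np.subtract.outer(np.arange(nr), np.arange(nr))))
    lc = np.linalg.cholesky(rho_col ** np.abs(np.subtract.outer(np.arange(nc), np.arange(nc))))
    field_noise = np.sqrt(sigma2) * (lr @ rng.standard_normal((nr, nc)) @ lc.T)
    noise = field_noise[rows - 1, cols - 1]
    values = spatial_trend(layout, trend_coeffs) + noise
    return pd.Series(values, index=layout.tree_ids, name="surface")


# ---------------------------------------------------------------------------
# trait assembly


@dataclass(frozen=True)
class TraitTable:
    """Per-tree trait values for one sampling month (wide format)."""

    data: pd.DataFrame  # index tree_id, columns = trait names
    month: str = "august"

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path, long: bool = False) -> None:
        if long:
            out = self.data.reset_index().melt(
                id_vars="tree_id", var_name="trait", value_name="value"
            )
            out.insert(1, "month", self.month)
            out.to_csv(path, index=False)
        else:
            self.data.reset_index().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, month: str = "august") -> "TraitTable":
        df = pd.read_csv(path)
        if {"trait", "value"} <= set(df.columns):  # long format
            month = df["month"].iloc[0] if "month" in df.columns else month
            wide = df.pivot(index="tree_id", columns="trait", values="value")
            return cls(wide, month)
        return cls(df.set_index("tree_id"), month)


def simulate_traits(
    layout: TrialLayout,
    genetic_values: pd.DataFrame,
    surfaces: Mapping[str, pd.Series],
    means: Mapping[str, float],
    ecotype_effects: Mapping[str, Mapping[str, float]] | None = None,
    month: str = "august",
) -> TraitTable:
    """Assemble per-tree trait values: mean + ecotype shift + genetics + surface."""
    traits = list(genetic_values.columns)
    if set(surfaces) != set(traits):
        raise ValueError("need exactly one spatial surface per trait")
    missing_clones = set(layout.table["clone_id"]) - set(genetic_values.index)
    if missing_clones:
        raise ValueError(f"genetic values missing for clones {sorted(missing_clones)}")
    data = {}
    clone_of = layout.table.set_index("tree_id")["clone_id"]
    eco_of = layout.table.set_index("tree_id")["ecotype"]
    for trait in traits:
        g = genetic_values.loc[clone_of, trait].to_numpy()
        s = surfaces[trait].reindex(clone_of.index).to_numpy()
        if np.any(np.isnan(s)):
            raise ValueError(f"surface for {trait!r} does not cover all trees")
        shift = 0.0
        if ecotype_effects and trait in ecotype_effects:
            shift = eco_of.map(lambda e: ecotype_effects[trait].get(e, 0.0)).to_numpy()
        data[trait] = means.get(trait, 0.0) + shift + g + s
    return TraitTable(pd.DataFrame(data, index=clone_of.index.copy()), month=month)


# ---------------------------------------------------------------------------
# spectra


@dataclass(frozen=True)
class SpectralLink:
    """Coefficients tying traits to reflectance absorption features.

    ``pigment_vis``: absorption depth at 680 nm per mg/g total chlorophyll
    (the 550-nm feature uses half this coefficient); ``water_swir``: depth of
    the 1450/1930-nm bands per unit latent water (970/1200 nm use 0.3x/0.4x);
    ``structure_nir``: NIR-plateau lift per unit latent structure.
    """

    pigment_vis: float = 0.010
    water_swir: float = 0.030
    structure_nir: float = 0.020


def _gauss(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def baseline_reflectance(grid: np.ndarray = DEFAULT_GRID) -> np.ndarray:
    """Vegetation-like baseline BRF curve: low VIS with a green bump, logistic
    red-edge rise to a NIR plateau, smooth SWIR decay."""
    lam = np.asarray(grid, dtype=float)
    return (
        0.08
        + 0.05 * _gauss(lam, 550.0, 35.0)
        + 0.37 * _sigmoid((lam - 715.0) / 13.0)
        - 0.25 * _sigmoid((lam - 1500.0) / 180.0)
    )


def _nir_plateau_shape(lam: np.ndarray) -> np.ndarray:
    return _sigmoid((lam - 715.0) / 13.0) * (1.0 - _sigmoid((lam - 1400.0) / 150.0))


#: (center nm, width nm, coefficient multiplier) of the water absorption bands
WATER_BANDS = ((970.0, 45.0, 0.3), (1200.0, 50.0, 0.4), (1450.0, 60.0, 1.0), (1930.0, 70.0, 1.0))


def simulate_spectra(
    traits: TraitTable,
    link: SpectralLink = SpectralLink(),
    noise_sd: float = 0.005,
    seed: int = 0,
    grid: np.ndarray = DEFAULT_GRID,
) -> SpectraMatrix:
    """Per-tree reflectance spectra driven by pigment, water, and structure.

    Requires trait columns ``chl_a`` and ``chl_b`` (mg/g dry mass) and latent
    ``water`` and ``structure`` variables (unit variance, mean 0). Reflectance
    is clipped to [0, 1] after adding iid Gaussian noise.
    """
    needed = {"chl_a", "chl_b", "water", "structure"}
    if missing := needed - set(traits.data.columns):
        raise ValueError(f"trait table missing spectral drivers {sorted(missing)}")
    lam = np.asarray(grid, dtype=float)
    base = baseline_reflectance(lam)
    chl = (traits.data["chl_a"] + traits.data["chl_b"]).to_numpy()[:, None]
    water = traits.data["water"].to_numpy()[:, None]
    structure = traits.data["structure"].to_numpy()[:, None]

    refl = np.broadcast_to(base, (len(traits.data), lam.size)).copy()
    refl -= link.pigment_vis * chl * _gauss(lam, 680.0, 28.0)
    refl -= 0.5 * link.pigment_vis * chl * _gauss(lam, 550.0, 30.0)
    for center, width, mult in WATER_BANDS:
        refl -= mult * link.water_swir * water * _gauss(lam, center, width)
    refl += link.structure_nir * structure * _nir_plateau_shape(lam)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        refl = refl + rng.normal(0.0, noise_sd, size=refl.shape)
    refl = np.clip(refl, 0.0, 1.0)
    out = pd.DataFrame(refl, index=traits.data.index.copy(), columns=np.asarray(grid, dtype=int))
    return SpectraMatrix(out)


# ---------------------------------------------------------------------------
# full-trial truth and one-call dataset generation


def _nearest_psd_correlation(C: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore a unit diagonal."""
    w, v = np.linalg.eigh((C + C.T) / 2.0)
    C2 = (v * np.clip(w, 1e-8, None)) @ v.T
    d = np.sqrt(np.diag(C2))
    return C2 / np.outer(d, d)


@dataclass(frozen=True)
class TruthParams:
    """Generative ground truth for one synthetic trial.

    Variances are in squared trait units; ``h2`` gives each trait's
    broad-sense heritability sigma2_c / (sigma2_c + sigma2), from which the
    clone and residual variances are derived off the phenotypic variance.
    """

    n_rows: int = 10
    n_cols: int = 10
    n_clones: int = 30
    ramets_per_clone: int = 3
    trait_names: tuple[str, ...] = (
        "dbh", "height", "hc", "lc", "chl_a", "chl_b", "car", "water", "structure",
    )
    means: Mapping[str, float] = field(default_factory=dict)
    phenotypic_var: Mapping[str, float] = field(default_factory=dict)
    h2: Mapping[str, float] = field(default_factory=dict)
    genetic_correlation: np.ndarray | None = None
    rho_row: float = 0.5
    rho_col: float = 0.5
    trend_sd_fraction: float = 0.3
    ecotype_effects: Mapping[str, Mapping[str, float]] | None = None
    ecotype_fractions: Mapping[str, float] | None = None
    clonal_rows: bool = False
    link: SpectralLink = SpectralLink()
    spectral_noise_sd: float = 0.005
    seed: int = 0

    def genetic_covariance(self) -> np.ndarray:
        sds = np.array(
            [np.sqrt(self.h2[t] * self.phenotypic_var[t]) for t in self.trait_names]
        )
        C = self.genetic_correlation
        if C is None:
            C = np.eye(len(self.trait_names))
        return _validate_covariance(np.outer(sds, sds) * C)

    def residual_variance(self, trait: str) -> float:
        return (1.0 - self.h2[trait]) * self.phenotypic_var[trait]


def default_truth(seed: int = 0, **overrides) -> TruthParams:
    """Realistic defaults for a mature clonal Norway-spruce trial.

    Trait means/spreads follow typical values for a ~50-year-old trial (DBH
    ~33 cm, height ~20 m); heritabilities sit in the 0.3-0.45 range reported
    for growth and pigment traits of clonal spruce material; pigments are
    mutually highly genetically correlated and moderately correlated with
    crown length; the latent water variable correlates with crown length and
    pigments so SWIR reflectance carries a genetic signal.
    """
    traits = ("dbh", "height", "hc", "lc", "chl_a", "chl_b", "car", "water", "structure")
    means = {
        "dbh": 33.1, "height": 20.6, "hc": 8.6, "lc": 12.0,
        "chl_a": 3.1, "chl_b": 1.1, "car": 0.57, "water": 0.0, "structure": 0.0,
    }
    pvar = {
        "dbh": 59.3, "height": 8.7, "hc": 5.3, "lc": 5.8,
        "chl_a": 0.64, "chl_b": 0.09, "car": 0.02, "water": 1.0, "structure": 1.0,
    }
    h2 = {
        "dbh": 0.33, "height": 0.41, "hc": 0.41, "lc": 0.36,
        "chl_a": 0.31, "chl_b": 0.36, "car": 0.29, "water": 0.40, "structure": 0.40,
    }
    k = len(traits)
    C = np.eye(k)
    ix = {t: i for i, t in enumerate(traits)}

    def set_r(a, b, r):
        C[ix[a], ix[b]] = C[ix[b], ix[a]] = r

    set_r("height", "dbh", 0.90)
    set_r("height", "hc", 0.75)
    set_r("height", "lc", 0.85)
    set_r("dbh", "hc", 0.40)
    set_r("dbh", "lc", 0.80)
    set_r("hc", "lc", 0.45)
    for a in ("chl_a", "chl_b", "car"):
        for b in ("chl_a", "chl_b", "car"):
            if a < b:
                set_r(a, b, 0.95)
        set_r(a, "lc", 0.65)
        set_r(a, "water", 0.40)
    set_r("water", "lc", 0.60)
    C = _nearest_psd_correlation(C)

    ecotype_effects = {
        "dbh": {"high": -6.0},
        "height": {"high": -3.7},
        "lc": {"high": -5.2},
        "chl_a": {"medium": -0.45},
        "chl_b": {"medium": -0.17},
        "car": {"medium": -0.07},
    }
    params = dict(
        trait_names=traits,
        means=means,
        phenotypic_var=pvar,
        h2=h2,
        genetic_correlation=C,
        ecotype_effects=ecotype_effects,
        seed=seed,
    )
    params.update(overrides)
    return TruthParams(**params)


@dataclass(frozen=True)
class TrialDataset:
    """One simulated trial: layout, clone genetic values, traits, spectra."""

    truth: TruthParams
    layout: TrialLayout
    genetic_values: pd.DataFrame
    traits: TraitTable
    spectra: SpectraMatrix


def simulate_dataset(truth: TruthParams, month: str = "august") -> TrialDataset:
    """Generate a complete trial from ``truth`` (deterministic in truth.seed).

    The sampling month shifts nothing by itself; callers emulating seasonal
    resampling draw a second dataset with a different seed/means and match
    tree ids.
    """
    base = np.random.SeedSequence(truth.seed).generate_state(5)
    layout = simulate_layout(
        truth.n_rows, truth.n_cols, truth.n_clones, truth.ramets_per_clone,
        ecotype_fractions=truth.ecotype_fractions, seed=int(base[0]),
        clonal_rows=truth.clonal_rows,
    )
    clone_ids = sorted(layout.table["clone_id"].unique())
    G = truth.genetic_covariance()
    gv = simulate_genetic_values(clone_ids, G, seed=int(base[1]), trait_names=truth.trait_names)
    surf_seeds = np.random.SeedSequence(int(base[2])).generate_state(len(truth.trait_names))
    surfaces = {}
    for t, s in zip(truth.trait_names, surf_seeds):
        sd = np.sqrt(truth.phenotypic_var[t])
        amp = truth.trend_sd_fraction * sd
        surfaces[t] = simulate_spatial_surface(
            layout, truth.rho_row, truth.rho_col, truth.residual_variance(t),
            trend_coeffs=(0.8 * amp, -0.5 * amp, 0.6 * amp, 0.4 * amp), seed=int(s),
        )
    traits = simulate_traits(
        layout, gv, surfaces, truth.means, truth.ecotype_effects, month=month
    )
    spectra = simulate_spectra(
        traits, truth.link, noise_sd=truth.spectral_noise_sd, seed=int(base[3])
    )
    return TrialDataset(truth, layout, gv, traits, spectra)
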