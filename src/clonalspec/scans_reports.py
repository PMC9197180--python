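"""Wavelength-wise and index-wise analyses: seasonal and ecotype comparisons,
correlation / heritability / genetic-correlation scans, and region reports.

All scans return tidy DataFrames (one row per wavelength, index, or group
pair) ready to be written as CSV; per-column model failures are recorded in
the output rather than aborting a scan. Wavelength-wise p-values are
reported raw (no multiple-testing correction) by default, with an optional
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .gcorr_bivariate import (
    UndefinedCorrelationError,
    genetic_correlation,
    genetic_correlation_with_test,
    reml_fit_bivariate,
    stack_bivariate,
)
from .lmm_spatial import ModelSpec, heritability, likelihood_ratio_test, reml_fit
from .synth_trial import TrialLayout


class SampleSizeError(ValueError):
    """Too few observations or groups for the requested comparison."""


# ---------------------------------------------------------------------------
# paired seasonal t-test per wavelength


def paired_t_scan(
    values_month1: pd.DataFrame,
    values_month2: pd.DataFrame,
    matched_tree_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Paired t-test per column between two sampling dates.

    Trees are matched by id; unmatched trees are dropped. Columns with
    zero-variance differences get p = 1 and ``degenerate = True``.
    Returns one row per column: ``column, mean_diff, t, p, n, degenerate``.
    """
    if matched_tree_ids is None:
        matched_tree_ids = values_month1.index.intersection(values_month2.index)
    # canonical tree order makes the scan invariant to input row permutations
    matched = pd.Index(sorted(matched_tree_ids))
    if len(matched) < 3:
        raise SampleSizeError("need at least 3 matched trees for the paired test")
    cols = values_month1.columns
    if not cols.equals(values_month2.columns):
        raise ValueError("the two tables must share columns")
    d = values_month2.loc[matched, cols].to_numpy() - values_month1.loc[matched, cols].to_numpy()
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"column": cols, "mean_diff": mean, "t": t, "p": p, "n": n, "degenerate": degenerate}
    )


# ---------------------------------------------------------------------------
# Fisher's LSD


@dataclass(frozen=True)
class PairwiseComparison:
    """One unadjusted pairwise contrast from a one-way layout."""

    trait: str
    group1: str
    group2: str
    difference: float
    se: float
    t: float
    p: float
    degenerate: bool = False


def lsd_compare(
    values: pd.Series,
    groups: pd.Series,
    trait: str | None = None,
    welch: bool = False,
    tail: str = "two-sided",
) -> list[PairwiseComparison]:
    """Fisher's LSD: pairwise t-tests with the pooled one-way error variance.

    With ``welch=True`` each pair uses Welch's unequal-variance t instead of
    the pooled variance. ``tail`` is "two-sided" (default) or "one-sided"
    (half the two-sided p). Zero pooled variance yields degenerate records
    with p = 1.
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    labels = list(pd.unique(df["group"]))
    if len(labels) < 2:
        raise SampleSizeError("need at least 2 groups")
    by = {g: df.loc[df["group"] == g, "value"].to_numpy() for g in labels}
    for g, v in by.items():
        if len(v) < 2:
            raise SampleSizeError(f"group {g!r} has fewer than 2 observations")
    N = len(df)
    k = len(labels)
    mse = sum(((v - v.mean()) ** 2).sum() for v in by.values()) / (N - k)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            g1, g2 = labels[i], labels[j]
            v1, v2 = by[g1], by[g2]
            diff = v1.mean() - v2.mean()
            if welch:
                se2 = v1.var(ddof=1) / len(v1) + v2.var(ddof=1) / len(v2)
                se = np.sqrt(se2)
                if se == 0:
                    out.append(PairwiseComparison(trait or str(values.name), g1, g2,
                                                  float(diff), 0.0, 0.0, 1.0, True))
                    continue
                dof = se2**2 / (
                    (v1.var(ddof=1) / len(v1)) ** 2 / (len(v1) - 1)
                    + (v2.var(ddof=1) / len(v2)) ** 2 / (len(v2) - 1)
                )
            else:
                se = np.sqrt(mse * (1.0 / len(v1) + 1.0 / len(v2)))
                dof = N - k
                if se == 0:
                    out.append(PairwiseComparison(trait or str(values.name), g1, g2,
                                                  float(diff), 0.0, 0.0, 1.0, True))
                    continue
            t = diff / se
            p = 2.0 * stats.t.sf(abs(t), dof)
            if tail == "one-sided":
                p /= 2.0
            elif tail != "two-sided":
                raise ValueError("tail must be 'two-sided' or 'one-sided'")
            out.append(PairwiseComparison(trait or str(values.name), g1, g2,
                                          float(diff), float(se), float(t), float(p)))
    return out


def lsd_table(comparisons: list[PairwiseComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])


# ---------------------------------------------------------------------------
# Pearson correlation scan


def pearson_scan(columns: pd.DataFrame, trait: pd.Series) -> pd.DataFrame:
    """Pearson correlation of ``trait`` against every column.

    Per column: ``r``, ``se = sqrt((1-r^2)/(n-2))``, two-sided p from
    ``t = r*sqrt((n-2)/(1-r^2))``, and the complete-pair count ``n``.
    Constant columns (or |r| = 1) are flagged undefined/degenerate with
    missing SE/p as appropriate.
    """
    out = []
    for col in columns.columns:
        pair = pd.DataFrame({"x": columns[col], "y": trait}).dropna()
        n = len(pair)
        if n < 3:
            out.append({"column": col, "r": np.nan, "se": np.nan, "p": np.nan,
                        "n": n, "undefined": True})
            continue
        x = pair["x"].to_numpy()
        y = pair["y"].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            out.append({"column": col, "r": np.nan, "se": np.nan, "p": np.nan,
                        "n": n, "undefined": True})
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) >= 1.0:
            out.append({"column": col, "r": r, "se": 0.0, "p": 0.0,
                        "n": n, "undefined": False})
            continue
        se = np.sqrt((1.0 - r**2) / (n - 2))
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
        out.append({"column": col, "r": r, "se": float(se), "p": float(p),
                    "n": n, "undefined": False})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# heritability scan


def heritability_scan(
    columns: pd.DataFrame,
    layout: TrialLayout,
    residual: str = "ar1xar1",
    alpha: float = 0.05,
    starts: Sequence[Sequence[float]] | None = None,
) -> pd.DataFrame:
    """Univariate spatial REML fit + heritability per column.

    Each column gets H2, its delta-method SE, the boundary-mixture LRT
    p-value for the clone variance, and a ``heritable`` flag (p < alpha,
    the pre-selection rule for index scans). Per-column failures are
    recorded (``error`` column), never fatal.
    """
    spec = ModelSpec("column", residual=residual)
    spec_nc = ModelSpec("column", residual=residual, clone_effect=False)
    rows = []
    for col in columns.columns:
        rec = {"column": col, "h2": np.nan, "se": np.nan, "p_clone": np.nan,
               "sigma2_c": np.nan, "sigma2": np.nan, "rho_row": np.nan,
               "rho_col": np.nan, "heritable": False, "error": ""}
        try:
            y = columns[col]
            if y.dropna().nunique() <= 1:
                raise ValueError("constant column; variance components undefined")
            fit = reml_fit(y, spec, layout, starts=starts)
            fit0 = reml_fit(y, spec_nc, layout)
            lrt = likelihood_ratio_test(fit, fit0, boundary=True, df=1)
            est = heritability(fit, p_clone=lrt.p)
            rec.update(h2=est.h2, se=est.se, p_clone=lrt.p,
                       sigma2_c=fit.sigma2_c, sigma2=fit.sigma2,
                       rho_row=fit.rho_row, rho_col=fit.rho_col,
                       heritable=bool(lrt.p < alpha))
        except Exception as exc:  # per-column failure record
            rec["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genetic-correlation scan


def gcorr_scan(
    columns: pd.DataFrame,
    trait: pd.Series,
    layout: TrialLayout,
    residual: str = "ar1xar1",
    lrt: bool = True,
    maxiter: int = 300,
) -> pd.DataFrame:
    """Bivariate REML fit of ``trait`` against every column.

    Records r_g, its SE, the boundary flag, and (optionally) the 1-df LRT
    p-value for zero clonal covariance. Failures become per-column records.
    """
    rows = []
    for col in columns.columns:
        rec = {"column": col, "r_g": np.nan, "se": np.nan, "flag": "",
               "p": np.nan, "error": ""}
        try:
            stacked = stack_bivariate(trait, columns[col], layout,
                                      trait_names=(str(trait.name or "trait"), str(col)))
            if lrt:
                fit, gc = genetic_correlation_with_test(stacked, residual=residual,
                                                        maxiter=maxiter)
            else:
                fit = reml_fit_bivariate(stacked, residual=residual, maxiter=maxiter)
                gc = genetic_correlation(fit)
            rec.update(r_g=gc.r_g, se=np.nan if gc.se is None else gc.se,
                       flag=gc.flag, p=np.nan if gc.p is None else gc.p)
        except UndefinedCorrelationError as exc:
            rec["error"] = f"UndefinedCorrelationError: {exc}"
        except Exception as exc:
            rec["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# significant regions


@dataclass(frozen=True)
class SignificanceRegions:
    """Maximal runs of consecutive grid wavelengths with p < alpha."""

    alpha: float
    intervals: tuple[tuple[int, int], ...]  # inclusive [start_nm, end_nm]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"alpha": self.alpha, "start_nm": a, "end_nm": b} for a, b in self.intervals]
        )

    def wavelength_set(self, grid: Sequence[int]) -> set[int]:
        g = np.asarray(grid)
        out: set[int] = set()
        for a, b in self.intervals:
            out.update(int(x) for x in g[(g >= a) & (g <= b)])
        return out


def significant_regions(
    pvalues: Sequence[float], grid: Sequence[int], alpha: float = 0.05,
    adjust: str | None = None,
) -> SignificanceRegions:
    """Contiguous significant wavelength intervals, endpoints inclusive.

    ``adjust="bh"`` applies Benjamini-Hochberg before thresholding (off by
    default: raw per-wavelength p-values are the reporting convention here).
    """
    p = np.asarray(pvalues, dtype=float)
    g = np.asarray(grid)
    if p.shape != g.shape:
        raise ValueError("p-values and grid must align")
    if adjust == "bh":
        p = _benjamini_hochberg(p)
    elif adjust is not None:
        raise ValueError("adjust must be None or 'bh'")
    mask = p < alpha
    intervals = []
    i = 0
    n = len(g)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1] and g[j + 1] == g[j] + 1:
                j += 1
            intervals.append((int(g[i]), int(g[j])))
            i = j + 1
        else:
            i += 1
    return SignificanceRegions(alpha=alpha, intervals=tuple(intervals))


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# run manifest


def write_manifest(path, seed: int | None = None, inputs: dict | None = None,
                   outputs: list[str] | None = None) -> dict:
    """JSON run manifest (inputs, package/python versions, seed) beside outputs."""
    manifest = {
        "package": "clonalspec",
        "version": _pkg_version,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "inputs": inputs or {},
        "outputs": outputs or [],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
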