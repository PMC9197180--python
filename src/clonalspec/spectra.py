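"""Spectral data model and vegetation-index computation.

Reflectance is stored as the bidirectional reflectance factor (BRF, unitless,
nominally 0-1) on an integer-nanometre grid, by default the full-range field
spectroradiometer grid 350-2500 nm at 1-nm steps (2151 bands).

Vegetation indices are kept in a registry with two dialects:

* ``"reported"`` (default) — the simple ratio/difference forms this
  pipeline standardizes on (e.g. CRI2 = R760/R700 - 1);
* ``"canonical"`` — the literature definitions where they differ (e.g. the
  canonical carotenoid reflectance index CRI2 = 1/R510 - 1/R700).

The dialects disagree only for CRI2; the ambiguity is deliberate and exposed
rather than silently resolved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_GRID = np.arange(350, 2501)  # nm, 2151 bands


class GridMismatchError(ValueError):
    """Scans or spectra do not share a common wavelength grid."""


@dataclass(frozen=True)
class IndexDefinition:
    """A vegetation index: a named scalar function of reflectances R(lambda)."""

    name: str
    formula: str
    wavelengths: tuple[int, ...]
    func: Callable[..., np.ndarray] = field(repr=False)
    dialect: str = "reported"


class SpectraMatrix:
    """Trees x wavelengths reflectance table.

    Parameters
    ----------
    values
        DataFrame indexed by tree id with integer wavelength columns (nm),
        strictly increasing. Values are BRF fractions; percent-scale input
        (max > 1.5) is auto-detected and divided by 100 with a warning.
    """

    def __init__(self, values: pd.DataFrame):
        cols = np.asarray([int(c) for c in values.columns])
        if cols.size == 0:
            raise ValueError("spectra need at least one wavelength column")
        if np.any(np.diff(cols) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        values = values.copy()
        values.columns = cols
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("reflectance values must be finite")
        if arr.size and np.nanmax(arr) > 1.5:
            logger.warning("spectra look percent-scaled (max %.3g); dividing by 100", arr.max())
            values = values / 100.0
            arr = values.to_numpy(dtype=float)
        if arr.size and (arr.min() < 0 or arr.max() > 1.1):
            warnings.warn(
                "reflectance outside the expected [0, 1.1] BRF range", stacklevel=2
            )
        self.values = values

    @property
    def wavelengths(self) -> np.ndarray:
        return self.values.columns.to_numpy()

    @property
    def tree_ids(self) -> pd.Index:
        return self.values.index

    def __len__(self) -> int:
        return len(self.values)

    def resolve_wavelength(self, nm: int | float) -> int:
        """Exact integer match, else nearest grid point within 1 nm, else error."""
        grid = self.wavelengths
        i = int(np.argmin(np.abs(grid - nm)))
        if abs(grid[i] - nm) > 1:
            raise KeyError(f"wavelength {nm} nm not on grid (nearest: {grid[i]} nm)")
        return int(grid[i])

    def reflectance(self, nm: int | float) -> pd.Series:
        """Per-tree reflectance at (the grid point nearest to) ``nm``."""
        return self.values[self.resolve_wavelength(nm)]

    def subset(self, lo: int, hi: int) -> "SpectraMatrix":
        """Wavelength window [lo, hi] nm, inclusive."""
        keep = [c for c in self.values.columns if lo <= c <= hi]
        return SpectraMatrix(self.values[keep])

    # -- CSV contract: first column tree_id, remaining columns "350".."2500"
    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "tree_id", out.index)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraMatrix":
        df = pd.read_csv(path)
        df = df.set_index("tree_id")
        return cls(df)


def median_spectrum(scans: Sequence[pd.Series | np.ndarray]) -> pd.Series | np.ndarray:
    """Per-wavelength median of repeated scans of one sample.

    Even scan counts use the midpoint of the two central order statistics.
    All scans must share one wavelength grid.
    """
    if len(scans) == 0:
        raise ValueError("need at least one scan")
    first = scans[0]
    if isinstance(first, pd.Series):
        idx = first.index
        for s in scans[1:]:
            if not isinstance(s, pd.Series) or not s.index.equals(idx):
                raise GridMismatchError("scans do not share a wavelength grid")
        stacked = np.vstack([np.asarray(s, dtype=float) for s in scans])
        return pd.Series(np.median(stacked, axis=0), index=idx)
    n = np.asarray(first).shape
    for s in scans[1:]:
        if np.asarray(s).shape != n:
            raise GridMismatchError("scans do not share a wavelength grid")
    return np.median(np.vstack([np.asarray(s, dtype=float) for s in scans]), axis=0)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Ratio with zero denominators mapped to NaN (flagged missing, not raised)."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = den != 0
    np.divide(num, den, out=out, where=ok)
    return out


def _tcari2(r750, r705, r550):
    inner = (r750 - r705) - 0.2 * (r750 - r550) * _safe_ratio(r750, r705)
    return 3.0 * inner


_REPORTED_INDICES: dict[str, IndexDefinition] = {}
_CANONICAL_INDICES: dict[str, IndexDefinition] = {}


def _register(table: dict, name: str, formula: str, wavelengths: tuple[int, ...], func, dialect: str):
    table[name] = IndexDefinition(name, formula, wavelengths, func, dialect)


# Default registry: simple ratio/difference forms over BRF.
_register(_REPORTED_INDICES, "CRI2", "R760/R700 - 1", (760, 700),
          lambda r760, r700: _safe_ratio(r760, r700) - 1.0, "reported")
_register(_REPORTED_INDICES, "DWSI4", "R550/R680", (550, 680),
          lambda r550, r680: _safe_ratio(r550, r680), "reported")
_register(_REPORTED_INDICES, "GI", "R554/R677", (554, 677),
          lambda r554, r677: _safe_ratio(r554, r677), "reported")
_register(_REPORTED_INDICES, "SR3", "R750/R550", (750, 550),
          lambda r750, r550: _safe_ratio(r750, r550), "reported")
_register(_REPORTED_INDICES, "SR4", "R700/R670", (700, 670),
          lambda r700, r670: _safe_ratio(r700, r670), "reported")
_register(_REPORTED_INDICES, "SR5", "R675/R700", (675, 700),
          lambda r675, r700: _safe_ratio(r675, r700), "reported")
_register(_REPORTED_INDICES, "TCARI2", "3*[(R750-R705) - 0.2*(R750-R550)*(R750/R705)]",
          (750, 705, 550), _tcari2, "reported")

# Canonical literature dialect: identical except for CRI2.
_CANONICAL_INDICES.update(_REPORTED_INDICES)
_register(_CANONICAL_INDICES, "CRI2", "1/R510 - 1/R700", (510, 700),
          lambda r510, r700: _safe_ratio(1.0, r510) - _safe_ratio(1.0, r700), "canonical")

_DIALECTS: Mapping[str, Mapping[str, IndexDefinition]] = {
    "reported": _REPORTED_INDICES,
    "canonical": _CANONICAL_INDICES,
}

INDEX_NAMES: tuple[str, ...] = tuple(_REPORTED_INDICES)


def index_definition(name: str, dialect: str = "reported") -> IndexDefinition:
    try:
        table = _DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown index dialect {dialect!r}") from None
    try:
        return table[name]
    except KeyError:
        raise KeyError(f"unknown vegetation index {name!r}") from None


def compute_index(spectra: SpectraMatrix, name: str, dialect: str = "reported") -> pd.Series:
    """Vegetation index per tree; zero denominators yield NaN."""
    defn = index_definition(name, dialect)
    args = [spectra.reflectance(nm).to_numpy() for nm in defn.wavelengths]
    return pd.Series(defn.func(*args), index=spectra.tree_ids, name=name)


def compute_indices(
    spectra: SpectraMatrix,
    names: Iterable[str] | None = None,
    dialect: str = "reported",
) -> pd.DataFrame:
    """Trees x indices table for a set of registry indices (default: all)."""
    names = list(names) if names is not None else list(INDEX_NAMES)
    return pd.DataFrame({n: compute_index(spectra, n, dialect) for n in names})
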