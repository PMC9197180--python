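"""Photosynthetic-pigment quantification from 80%-acetone extract absorbances.

Needle powder (default 25 mg dry mass) is extracted in 80% (v/v) acetone made
up to a default 10 ml. Absorbances read at 663, 646, and 470 nm are converted
to extract concentrations (ug/ml) with a published coefficient set and then
related to dry mass, giving mg per g dry mass (ug/mg == mg/g).

Coefficient sets are pluggable because the few-percent differences between
published revisions matter downstream; the set name is stamped on every
result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

#: name -> (ca_663, ca_646, cb_646, cb_663, car_ca, car_cb, car_denom) such that
#:   Ca  = ca_663*A663 - ca_646*A646
#:   Cb  = cb_646*A646 - cb_663*A663
#:   Car = (1000*A470 - car_ca*Ca - car_cb*Cb) / car_denom
COEFFICIENT_SETS: dict[str, tuple[float, float, float, float, float, float, float]] = {
    # Lichtenthaler's 80%-acetone equations (default).
    "lichtenthaler": (12.25, 2.79, 21.50, 5.10, 1.82, 85.02, 198.0),
    # Wellburn 1994 recalibration for 80% acetone.
    "wellburn1994": (12.21, 2.81, 20.13, 5.03, 3.27, 104.0, 198.0),
}


@dataclass(frozen=True)
class PigmentAssay:
    """One spectrophotometric reading of a needle extract."""

    a663: float
    a646: float
    a470: float
    extract_volume_ml: float = 10.0
    dry_mass_mg: float = 25.0

    def __post_init__(self):
        for name in ("a663", "a646", "a470"):
            if getattr(self, name) < 0:
                raise ValueError(f"absorbance {name} must be >= 0")
        if self.extract_volume_ml <= 0:
            raise ValueError("extract volume must be > 0")
        if self.dry_mass_mg <= 0:
            raise ValueError("dry mass must be > 0")


@dataclass(frozen=True)
class PigmentResult:
    """Pigment content in mg per g needle dry mass.

    ``flagged`` is True when any computed value is negative (reported, never
    truncated, so downstream statistics stay unbiased).
    """

    chl_a: float
    chl_b: float
    carotenoids: float
    coefficient_set: str
    flagged: bool


def pigment_content(assay: PigmentAssay, coefficient_set: str = "lichtenthaler") -> PigmentResult:
    """Convert extract absorbances to pigment content per needle dry mass."""
    try:
        ca663, ca646, cb646, cb663, kca, kcb, den = COEFFICIENT_SETS[coefficient_set]
    except KeyError:
        raise ValueError(
            f"unknown coefficient set {coefficient_set!r}; "
            f"available: {sorted(COEFFICIENT_SETS)}"
        ) from None
    ca = ca663 * assay.a663 - ca646 * assay.a646
    cb = cb646 * assay.a646 - cb663 * assay.a663
    car = (1000.0 * assay.a470 - kca * ca - kcb * cb) / den
    scale = assay.extract_volume_ml / assay.dry_mass_mg  # ug/ml * ml / mg = mg/g
    vals = (ca * scale, cb * scale, car * scale)
    return PigmentResult(*vals, coefficient_set, flagged=any(v < 0 for v in vals))


def pigment_table(assays: pd.DataFrame, coefficient_set: str = "lichtenthaler") -> pd.DataFrame:
    """Vectorized conversion for a CSV-contract table.

    Expects columns ``tree_id, A663, A646, A470`` and optionally
    ``volume_ml, dry_mass_mg``; returns
    ``tree_id, chl_a, chl_b, car, coefficient_set, flag``.
    """
    rows = []
    for rec in assays.itertuples(index=False):
        assay = PigmentAssay(
            a663=rec.A663,
            a646=rec.A646,
            a470=rec.A470,
            extract_volume_ml=getattr(rec, "volume_ml", 10.0),
            dry_mass_mg=getattr(rec, "dry_mass_mg", 25.0),
        )
        res = pigment_content(assay, coefficient_set)
        rows.append(
            {
                "tree_id": rec.tree_id,
                "chl_a": res.chl_a,
                "chl_b": res.chl_b,
                "car": res.carotenoids,
                "coefficient_set": res.coefficient_set,
                "flag": res.flagged,
            }
        )
    return pd.DataFrame(rows)
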