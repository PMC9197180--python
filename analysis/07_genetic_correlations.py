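"""Genetic correlations from stacked bivariate spatial REML models.

Trait-pair genetic correlations (pigments x growth), the heritable-index
against pigment/growth table, and a thinned wavelength scan against
chlorophyll a. Boundary solutions (|r_g| clamped at 0.999) carry flag "B"
and no SE, the reporting convention for clonal covariances pinned to the
edge of the parameter space.
"""

import argparse
from itertools import combinations
from pathlib import Path

import pandas as pd

from clonalspec import gcorr_bivariate as gb
from clonalspec import scans_reports as sr
from clonalspec import spectra as sp
from clonalspec import synth_trial as st

PAIR_TRAITS = ("height", "dbh", "hc", "lc", "chl_a", "chl_b", "car")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--wavelength-step", type=int, default=100)
    args = ap.parse_args()

    layout = st.TrialLayout.from_csv(args.out_dir / "layout.csv")
    traits = st.TraitTable.from_csv(args.out_dir / "traits_august.csv")
    spectra = sp.SpectraMatrix.from_csv(args.out_dir / "spectra_august.csv")
    idx = (pd.read_csv(args.out_dir / "indices_august.csv")
           .pivot(index="tree_id", columns="index", values="value"))

    rows = []
    for t1, t2 in combinations(PAIR_TRAITS, 2):
        try:
            stacked = gb.stack_bivariate(traits.data[t1], traits.data[t2], layout,
                                         trait_names=(t1, t2))
            fit, gc = gb.genetic_correlation_with_test(stacked)
            rows.append({"trait1": t1, "trait2": t2, "r_g": gc.r_g,
                         "se": gc.se, "flag": gc.flag, "p": gc.p})
        except gb.UndefinedCorrelationError as exc:
            rows.append({"trait1": t1, "trait2": t2, "r_g": float("nan"),
                         "se": None, "flag": "", "p": None, "error": str(exc)})
    pairs = pd.DataFrame(rows)
    pairs.to_csv(args.out_dir / "gcorr_trait_pairs.csv", index=False)
    print("trait-pair genetic correlations (flag B = boundary):")
    show = pairs[["trait1", "trait2", "r_g", "se", "flag", "p"]].copy()
    print(show.round(3).to_string(index=False))

    for target in ("chl_a", "lc"):
        scan = sr.gcorr_scan(idx, traits.data[target], layout)
        scan.insert(0, "trait", target)
        scan.to_csv(args.out_dir / f"gcorr_indices_{target}.csv", index=False)
        print(f"\nindex genetic correlations with {target}:")
        print(scan[["column", "r_g", "se", "flag", "p"]].round(3).to_string(index=False))

    wl = spectra.values.loc[:, ::args.wavelength_step]
    wscan = sr.gcorr_scan(wl, traits.data["chl_a"], layout, lrt=False)
    wscan.to_csv(args.out_dir / "gcorr_wavelengths_chla.csv", index=False)
    ok = wscan.dropna(subset=["r_g"])
    print(f"\nwavelength scan vs chl_a ({len(wl.columns)} bands): r_g range "
          f"{ok['r_g'].min():+.2f} to {ok['r_g'].max():+.2f}, "
          f"{(ok['flag'] == 'B').sum()} boundary fits")


if __name__ == "__main__":
    main()
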