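"""Broad-sense heritability of traits, vegetation indices, and wavelengths.

Each column gets the univariate spatial REML fit (clone effect + AR1xAR1
residuals + second-order row/col polynomials), H2 = sigma2_c/(sigma2_c +
sigma2) with its delta-method SE, and the boundary-mixture LRT p-value for
the clone variance. Indices with p < alpha form the "heritable" subset used
for genetic-correlation follow-up. The wavelength scan runs on a thinned
grid to keep the run short; the per-column model is identical at any grid.
"""

import argparse
from pathlib import Path

import pandas as pd

from clonalspec import scans_reports as sr
from clonalspec import spectra as sp
from clonalspec import synth_trial as st

TRAITS = ("dbh", "height", "hc", "lc", "chl_a", "chl_b", "car")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--wavelength-step", type=int, default=50)
    args = ap.parse_args()

    layout = st.TrialLayout.from_csv(args.out_dir / "layout.csv")
    traits = st.TraitTable.from_csv(args.out_dir / "traits_august.csv")
    spectra = sp.SpectraMatrix.from_csv(args.out_dir / "spectra_august.csv")
    idx = (pd.read_csv(args.out_dir / "indices_august.csv")
           .pivot(index="tree_id", columns="index", values="value"))

    cols = pd.concat([traits.data[list(TRAITS)], idx], axis=1)
    scan = sr.heritability_scan(cols, layout)
    scan.to_csv(args.out_dir / "heritability_traits_indices.csv", index=False)
    print("trait/index heritabilities (H2, SE, clone-variance LRT p):")
    view = scan.set_index("column")[["h2", "se", "p_clone", "heritable"]].round(3)
    print(view.to_string())
    heritable = scan[scan["heritable"] & scan["column"].isin(sp.INDEX_NAMES)]
    print(f"\nheritable index subset: {', '.join(heritable['column'])}")

    wl = spectra.values.loc[:, ::args.wavelength_step]
    wscan = sr.heritability_scan(wl, layout)
    wscan.to_csv(args.out_dir / "heritability_wavelengths.csv", index=False)
    ok = wscan.dropna(subset=["h2"])
    print(f"\nwavelength scan ({len(wl.columns)} bands, step "
          f"{args.wavelength_step} nm): H2 range "
          f"{ok['h2'].min():.2f}-{ok['h2'].max():.2f}, "
          f"{int(ok['heritable'].sum())} bands heritable at p < 0.05")


if __name__ == "__main__":
    main()
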