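"""Phenotypic Pearson-correlation scans: spectra and indices against traits.

Per-wavelength Pearson correlations of the August reflectance with pigment
contents and growth traits, plus the index-by-trait correlation table with
SE = sqrt((1 - r^2)/(n - 2)).
"""

import argparse
from pathlib import Path

import pandas as pd

from clonalspec import scans_reports as sr
from clonalspec import spectra as sp
from clonalspec import synth_trial as st

TRAITS = ("chl_a", "chl_b", "car", "height", "hc", "lc", "dbh")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    traits = st.TraitTable.from_csv(args.out_dir / "traits_august.csv")
    spectra = sp.SpectraMatrix.from_csv(args.out_dir / "spectra_august.csv")
    idx = (pd.read_csv(args.out_dir / "indices_august.csv")
           .pivot(index="tree_id", columns="index", values="value"))

    scans = []
    for trait in TRAITS:
        scan = sr.pearson_scan(spectra.values, traits.data[trait])
        scan.insert(0, "trait", trait)
        scans.append(scan)
    all_scans = pd.concat(scans, ignore_index=True)
    all_scans.to_csv(args.out_dir / "pearson_wavelength_scans.csv", index=False)
    for trait in ("chl_a", "lc"):
        sub = all_scans[all_scans["trait"] == trait]
        peak = sub.loc[sub["r"].abs().idxmax()]
        print(f"{trait}: strongest wavelength correlation r = {peak['r']:+.3f} "
              f"at {int(peak['column'])} nm ({int((sub['p'] < 0.05).sum())} "
              f"significant wavelengths)")

    rows = []
    for trait in TRAITS:
        scan = sr.pearson_scan(idx, traits.data[trait])
        scan.insert(0, "trait", trait)
        rows.append(scan)
    index_table = pd.concat(rows, ignore_index=True)
    index_table.to_csv(args.out_dir / "pearson_indices.csv", index=False)
    pivot = index_table.pivot(index="trait", columns="column", values="r").round(3)
    print("\nindex-by-trait Pearson correlations:")
    print(pivot.to_string())


if __name__ == "__main__":
    main()
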