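"""Ecotype comparisons: Fisher-LSD pairwise tests on traits and per-wavelength.

Unadjusted pairwise t-tests with the pooled one-way error variance, first on
growth and pigment traits, then wavelength-by-wavelength on the August
spectra for each ecotype pair, with contiguous significant regions reported.
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
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    layout = st.TrialLayout.from_csv(args.out_dir / "layout.csv")
    traits = st.TraitTable.from_csv(args.out_dir / "traits_august.csv")
    spectra = sp.SpectraMatrix.from_csv(args.out_dir / "spectra_august.csv")
    eco = layout.table.set_index("tree_id")["ecotype"]

    comps = []
    for trait in TRAITS:
        comps += sr.lsd_compare(traits.data[trait], eco, trait=trait)
    table = sr.lsd_table(comps)
    table.to_csv(args.out_dir / "ecotype_lsd_traits.csv", index=False)
    sig = table[table["p"] < args.alpha]
    print(f"{len(sig)}/{len(table)} trait-level ecotype contrasts significant "
          f"at p < {args.alpha}:")
    for rec in sig.itertuples():
        print(f"  {rec.trait}: {rec.group1} vs {rec.group2} "
              f"diff {rec.difference:+.3f} (p = {rec.p:.4f})")

    region_rows = []
    grid = spectra.wavelengths
    pairs = [("low", "medium"), ("low", "high"), ("medium", "high")]
    for g1, g2 in pairs:
        keep = eco[eco.isin([g1, g2])]
        sub = spectra.values.loc[keep.index]
        pvals = []
        for wl in grid:
            (c,) = sr.lsd_compare(sub[wl], keep)
            pvals.append(c.p)
        regions = sr.significant_regions(pvals, grid, alpha=args.alpha)
        for a, b in regions.intervals:
            region_rows.append({"pair": f"{g1}-{g2}", "alpha": args.alpha,
                                "start_nm": a, "end_nm": b})
        spans = sum(b - a + 1 for a, b in regions.intervals)
        print(f"{g1} vs {g2}: {spans} significant wavelengths in "
              f"{len(regions.intervals)} regions")
    pd.DataFrame(region_rows).to_csv(args.out_dir / "ecotype_spectral_regions.csv",
                                     index=False)


if __name__ == "__main__":
    main()
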