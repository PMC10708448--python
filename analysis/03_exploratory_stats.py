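"""Exploratory statistics on 1 DAT: NDVI t-test heatmap and top discriminative bands.

Computes per-sample NDVI (670/800 nm) on day-1 spectra, runs Welch
t-tests over every unordered treatment pair, and fits a 100-tree
Random Forest (seed 42) per pair to find each pair's most important
wavelength.  Writes both matrices as CSV and annotated heatmap PNGs.

Reads results/study_spectra.csv (run 01_simulate_study.py first;
regenerates it if missing).
"""

import os

from hsisoa.evaluate import exclude_outliers
from hsisoa.preprocess import SpectraTable
from hsisoa.stats import (
    importance_heatmap,
    ndvi_table,
    pairwise_top_bands,
    pairwise_ttest,
    plot_pvalue_heatmap,
)

OUT = "results"
SPECTRA = os.path.join(OUT, "study_spectra.csv")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    if not os.path.exists(SPECTRA):
        from hsisoa.synthetic import StudyConfig, generate_study

        generate_study(StudyConfig(seed=1)).table.to_csv(SPECTRA)
    table = exclude_outliers(SpectraTable.from_csv(SPECTRA)).filter(dat=1)

    values = ndvi_table(table)
    groups = {
        name: values[table.meta["treatment"] == name].to_numpy()
        for name in table.meta["treatment"].unique()
    }
    pmat = pairwise_ttest(groups)
    pmat.to_frame().to_csv(os.path.join(OUT, "ndvi_pvalues_1dat.csv"))
    plot_pvalue_heatmap(
        pmat, os.path.join(OUT, "ndvi_pvalues_1dat.png"), "NDVI pairwise Welch t-test p-values, 1 DAT"
    )
    significant = int((pmat.pvalues < 0.05).sum() // 2)
    total = len(pmat.classes) * (len(pmat.classes) - 1) // 2
    print(f"NDVI separates {significant}/{total} treatment pairs at p < 0.05 on 1 DAT")

    bands = importance_heatmap(pairwise_top_bands(table))
    bands.to_csv(os.path.join(OUT, "top_bands_1dat.csv"))
    plot_pvalue_heatmap(bands, os.path.join(OUT, "top_bands_1dat.png"), "Top band (nm) per pair, 1 DAT")
    flat = bands.stack()
    print(f"top bands span {flat.min():.1f}-{flat.max():.1f} nm across pairs")
    print(f"wrote NDVI and band heatmaps under {OUT}/")


if __name__ == "__main__":
    main()
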