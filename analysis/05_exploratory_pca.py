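#!/usr/bin/env python
"""PCA of the normalised VOC matrix and correlation with clinical data.

Principal components over all 70 samples, per-subject 95% ellipses in the
PC1/PC2 plane, and the component x covariate correlation grid (Pearson for
continuous covariates, point-biserial for binary ones, sputum granulocytes
log transformed, subject identity as the one-vs-rest maximum).
"""

import warnings
from pathlib import Path

warnings.filterwarnings("ignore")

import pandas as pd

from vocrepeat import io
from vocrepeat.exploratory import (
    correlate_pcs,
    ellipses_frame,
    feno_association_flag,
    group_ellipses,
    run_pca,
)

IN = Path("results/analysis/normalized")
COHORT = Path("results/analysis/cohort")
OUT = Path("results/analysis/exploratory")


def main() -> None:
    scaled = io.read_table(IN / "normalized_values.tsv")
    samples = io.read_table(COHORT / "samples.tsv")
    clinical = pd.read_csv(COHORT / "clinical.tsv", sep="\t")
    subjects = samples["subject_id"]

    pca = run_pca(scaled, n_components=10)
    grid = correlate_pcs(pca.scores, clinical, subjects)
    ellipses = ellipses_frame(group_ellipses(pca.scores, subjects))

    io.write_table(pca.scores, OUT / "pca_scores.tsv")
    io.write_table(pca.loadings, OUT / "pca_loadings.tsv")
    io.write_table(
        pca.explained_variance_ratio.to_frame("explained_variance_ratio"),
        OUT / "pca_explained_variance.tsv",
    )
    io.write_table(grid, OUT / "correlation_grid.tsv", index=False)
    io.write_table(ellipses, OUT / "subject_ellipses.tsv", index=False)

    evr = pca.explained_variance_ratio
    print(
        "explained variance: PC1 %.1f%%, PC2 %.1f%% (first two: %.1f%%; first ten: %.1f%%)"
        % (100 * evr.iloc[0], 100 * evr.iloc[1], 100 * evr.iloc[:2].sum(), 100 * evr.sum())
    )
    lead = grid[grid.component.isin(["PC1", "PC2", "PC3"]) & grid.significant]
    print("significant correlations on PCs 1-3 (sample-level, unadjusted):")
    print(
        lead.sort_values("p")[["component", "covariate", "r", "p", "method"]]
        .head(10)
        .to_string(index=False)
    )
    flag = feno_association_flag(pca.scores, clinical, subjects)
    print(f"subject-level FeNO association flag (Holm over PCs 1-3): {flag}")
    print(f"wrote exploratory tables to {OUT}")


if __name__ == "__main__":
    main()
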