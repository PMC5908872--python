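"""PCA of DEG moderated-log expression.

Projects the 37 libraries on the first two principal components of the
centered, scaled expression of the DEG union and reports the variance each
component explains and the within- vs between-group sample distances.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from lymphomap import diffexpr, summaries
from lymphomap.io import (
    read_count_matrix, read_sample_sheet, read_table, setup_logging, write_table,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    setup_logging()
    counts = read_count_matrix(ROOT / "filter" / "counts_filtered.tsv")
    design = read_sample_sheet(ROOT / "data" / "samples.tsv")
    dirs = read_table(ROOT / "de" / "directions.tsv").astype("int8")
    sf = read_table(ROOT / "filter" / "size_factors.tsv")["size_factor"]

    union = dirs.index[(dirs != 0).any(axis=1)]
    logexpr = diffexpr.moderated_log(counts, sf).loc[union.intersection(counts.counts.index)]
    pca = summaries.pca_degs(logexpr, k=2)

    out = ROOT / "pca"
    out.mkdir(parents=True, exist_ok=True)
    write_table(pca.scores, out / "scores.tsv")
    pd.Series(
        pca.variance_fraction, index=["PC1", "PC2"], name="variance_fraction"
    ).to_frame().to_csv(out / "variance.tsv", sep="\t", float_format="%.17g")

    S = pca.scores.to_numpy()
    groups = design.sample_to_group.reindex(pca.scores.index).to_numpy()
    d = np.linalg.norm(S[:, None] - S[None, :], axis=2)
    same = groups[:, None] == groups[None, :]
    np.fill_diagonal(same, False)
    off = ~np.eye(len(S), dtype=bool)
    print(
        f"PCA over {logexpr.shape[0]} DEGs x {logexpr.shape[1]} libraries: "
        f"PC1 {100 * pca.variance_fraction[0]:.0f}%, "
        f"PC2 {100 * pca.variance_fraction[1]:.0f}% of variance"
    )
    print(
        f"mean sample distance within groups {d[same].mean():.2f} "
        f"vs between groups {d[off & ~same].mean():.2f}"
    )


if __name__ == "__main__":
    sys.exit(main())
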