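"""Per-group NB Wald differential expression vs. controls.

Fits size factors, dispersions and group means on the filtered matrix,
tests every gene in each of the seven contrasts at FDR <= 1e-5, and writes
the DE table, direction matrix and per-group DEG tallies under results/de/.
"""

import sys
from pathlib import Path

from lymphomap import diffexpr, summaries
from lymphomap.io import read_count_matrix, read_sample_sheet, setup_logging, write_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    setup_logging()
    counts = read_count_matrix(ROOT / "filter" / "counts_filtered.tsv")
    design = read_sample_sheet(ROOT / "data" / "samples.tsv")
    de, sf, alpha = diffexpr.run_de(counts, design, fdr=1e-5)
    dirs = de.directions()
    deg = summaries.deg_summary(dirs, de.table)
    out = ROOT / "de"
    out.mkdir(parents=True, exist_ok=True)
    write_table(de.table, out / "de_table.tsv", index=False)
    write_table(dirs, out / "directions.tsv")
    write_table(deg.per_group, out / "deg_summary.tsv")
    alpha.to_frame().to_csv(out / "dispersions.tsv", sep="\t", float_format="%.17g")
    print(
        f"{deg.union_all} genes differentially expressed in >= 1 of "
        f"{dirs.shape[1]} contrasts (FDR <= 1e-5)"
    )
    print(deg.per_group.to_string())


if __name__ == "__main__":
    sys.exit(main())
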