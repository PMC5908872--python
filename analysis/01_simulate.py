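"""Generate the synthetic study dataset.

Emits the 37-library experiment (seven lymphoma / lymphoid-cell-line groups
plus four controls), ~2,750 genes over three biotypes, 60 gene sets with
planted profile archetypes, and the ground truth, under results/data/.
"""

import sys
from pathlib import Path

from lymphomap.io import (
    setup_logging, write_count_matrix, write_gmt, write_sample_sheet, write_table,
)
from lymphomap.simulate import SimulationConfig, simulate_experiment, total_library_count

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    setup_logging()
    cfg = SimulationConfig(seed=SEED)
    counts, design, gene_sets, truth = simulate_experiment(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    write_count_matrix(counts, OUT / "counts.tsv")
    write_sample_sheet(design, OUT / "samples.tsv")
    write_gmt(gene_sets, OUT / "gene_sets.gmt")
    write_table(truth.beta, OUT / "truth_beta.tsv")
    truth.pathway_archetype.to_frame().to_csv(OUT / "truth_archetypes.tsv", sep="\t")
    truth.size_factors.to_frame().to_csv(OUT / "truth_size_factors.tsv", sep="\t")
    n_planted = int((truth.beta != 0).any(axis=1).sum())
    print(
        f"simulated {counts.n_genes} genes x {total_library_count(design)} libraries "
        f"({len(design.groups)} groups vs control), {len(gene_sets)} gene sets, "
        f"{n_planted} genes with planted fold changes -> {OUT}"
    )


if __name__ == "__main__":
    sys.exit(main())
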