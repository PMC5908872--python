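"""End-to-end orchestration: simulate -> filter -> DE -> downstream tables.

``run_all`` chains every stage with a single seed and writes all outputs as
TSV/JSON under one directory; the same seed gives byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, filtering, pathways, som, summaries
from .io import log, write_count_matrix, write_gmt, write_sample_sheet, write_table
from .simulate import SimulationConfig, SyntheticTruth, simulate_experiment
from .types import CountMatrix, GeneSetCollection, GroupDesign


@dataclass
class PipelineResult:
    counts_raw: CountMatrix
    counts_filtered: CountMatrix
    design: GroupDesign
    gene_sets: GeneSetCollection
    truth: SyntheticTruth | None
    size_factors: pd.Series
    dispersions: pd.Series
    de: diffexpr.DEResult
    directions: pd.DataFrame
    netexpr: pathways.NetExpressionMatrix
    som_model: som.SOMModel
    som_assignment: som.SOMAssignment
    deg: summaries.DEGSummary
    pca: summaries.PCAResult


def run_pipeline(
    counts: CountMatrix,
    design: GroupDesign,
    gene_sets: GeneSetCollection,
    seed: int = 0,
    fdr: float = 1e-5,
    percentile: float = 0.40,
    min_pathway_genes: int = 20,
    grid: tuple[int, int] = (4, 4),
    som_epochs: int = 100,
    shrink: float = 0.5,
    norm: str = "size-factor",
    truth: SyntheticTruth | None = None,
) -> PipelineResult:
    """Run every analysis stage on an in-memory dataset."""
    detected, _ = filtering.detection_filter(counts)
    if norm == "size-factor":
        sf = diffexpr.estimate_size_factors(detected)
    elif norm == "total-count":
        sf = diffexpr.total_count_size_factors(detected)
    else:
        raise ValueError(f"unknown normalization {norm!r}")
    filtered, _ = filtering.percentile_filter(detected, sf, q=percentile)
    de, sf, alpha = diffexpr.run_de(filtered, design, sf=sf, fdr=fdr, shrink=shrink)
    dirs = de.directions()

    universe = pathways.detected_universe(counts)
    ne = pathways.net_expression_matrix(
        dirs, gene_sets, universe, min_size=min_pathway_genes
    )
    model = som.train_som(
        ne.ne, rows=grid[0], cols=grid[1], epochs=som_epochs, seed=seed
    )
    assignment = som.assign_bmu(model, ne.ne)

    deg = summaries.deg_summary(dirs, de.table)
    deg_union = dirs.index[(dirs != 0).any(axis=1)]
    logexpr = diffexpr.moderated_log(filtered, sf).loc[deg_union]
    pca = summaries.pca_degs(logexpr, k=2) if len(deg_union) >= 2 else None

    return PipelineResult(
        counts_raw=counts,
        counts_filtered=filtered,
        design=design,
        gene_sets=gene_sets,
        truth=truth,
        size_factors=sf,
        dispersions=alpha,
        de=de,
        directions=dirs,
        netexpr=ne,
        som_model=model,
        som_assignment=assignment,
        deg=deg,
        pca=pca,
    )


def run_all(
    outdir,
    seed: int = 0,
    config: SimulationConfig | None = None,
    fdr: float = 1e-5,
    percentile: float = 0.40,
    min_pathway_genes: int = 20,
    grid: tuple[int, int] = (4, 4),
    som_epochs: int = 100,
    shrink: float = 0.5,
    norm: str = "size-factor",
) -> PipelineResult:
    """Simulate a dataset, run the full pipeline, and write all outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or SimulationConfig(seed=seed)
    cfg.seed = seed
    counts, design, gene_sets, truth = simulate_experiment(cfg)
    res = run_pipeline(
        counts,
        design,
        gene_sets,
        seed=seed,
        fdr=fdr,
        percentile=percentile,
        min_pathway_genes=min_pathway_genes,
        grid=grid,
        som_epochs=som_epochs,
        shrink=shrink,
        norm=norm,
        truth=truth,
    )
    write_outputs(res, outdir)
    echo = {
        "seed": seed,
        "fdr": fdr,
        "percentile": percentile,
        "min_pathway_genes": min_pathway_genes,
        "grid": list(grid),
        "som_epochs": som_epochs,
        "shrink": shrink,
        "norm": norm,
        "n_genes": dict(cfg.n_genes),
        "replicates": dict(cfg.replicates),
    }
    (outdir / "run_config.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))
    log.info("run_all: outputs written to %s", outdir)
    return res


def write_outputs(res: PipelineResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_matrix(res.counts_raw, outdir / "counts.tsv")
    write_sample_sheet(res.design, outdir / "samples.tsv")
    write_gmt(res.gene_sets, outdir / "gene_sets.gmt")
    write_table(res.de.table, outdir / "de_table.tsv", index=False)
    write_table(res.directions, outdir / "directions.tsv")
    write_table(res.netexpr.to_long(), outdir / "net_expression.tsv", index=False)
    assign = res.som_assignment.units.to_frame()
    assign["unit_band"] = res.som_assignment.summary["band"].reindex(
        res.som_assignment.units
    ).to_numpy()
    assign.index.name = "pathway"
    write_table(assign, outdir / "som_assignment.tsv")
    write_table(res.som_assignment.summary, outdir / "som_units.tsv")
    write_table(res.deg.per_group, outdir / "deg_summary.tsv")
    if res.pca is not None:
        write_table(res.pca.scores, outdir / "pca_scores.tsv")
        pd.Series(
            res.pca.variance_fraction,
            index=[f"PC{i + 1}" for i in range(len(res.pca.variance_fraction))],
            name="variance_fraction",
        ).to_frame().to_csv(outdir / "pca_variance.tsv", sep="\t", float_format="%.12g")
    (outdir / "som_model.json").write_text(
        json.dumps(res.som_model.to_dict(), indent=1, sort_keys=True)
    )
    if res.truth is not None:
        write_table(res.truth.beta, outdir / "truth_beta.tsv")
        res.truth.pathway_archetype.to_frame().to_csv(outdir / "truth_archetypes.tsv", sep="\t")
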