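"""Synthetic count data with the structure the downstream analysis assumes.

The generator emulates a bulk RNA-seq comparison of seven lymphoma /
lymphoid-cell-line sample groups against non-neoplastic controls
(replicates 12, 4, 5, 5, 1, 4, 2 plus 4 controls = 37 libraries), with
three gene biotypes, negative-binomial counts, library-size variation,
planted group-specific fold changes, and planted pathway-profile
archetypes. Counts for gene g in sample j of group G are drawn as

    K_gj ~ NB(mean = s_j * mu_g * 2^beta_gG,  var = mean + alpha_g * mean^2)

via the gamma-Poisson mixture, where mu_g is a log-normal baseline mean
(lower for miRNA/lncRNA), alpha_g a gamma-distributed dispersion, s_j a
log-normal library size factor, and beta_gG the planted log2 fold change
(0 for controls and for null genes).

Planted differential-expression structure (all among well-expressed
protein-coding genes, pools disjoint):

* core genes, up or down in ALL seven groups;
* per-group exclusive genes (random sign);
* cell-line-only genes, down in the five cell-line groups only;
* a couple of discordant genes, up everywhere except down in GL1 —
  mimicking genes whose sign flips in a single cell line.

Pathways are planted with profile archetypes: ``all_negative`` (members
drawn partly from the core-down pool), ``all_positive`` (core-up),
``near_zero`` (null members only), ``cell_line_only`` (cell-line-down pool)
and unconstrained ``background`` sets. Net expression computed from the
TRUE direction labels reproduces each archetype's sign pattern exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    BIOTYPES,
    CELL_LINE_GROUPS,
    ConfigError,
    CountMatrix,
    GeneSetCollection,
    GroupDesign,
)

#: Replicate structure of the emulated study: 33 tumor/cell-line libraries
#: plus 4 control libraries, 37 in total.
DEFAULT_REPLICATES = {
    "B_lymphoma": 12,
    "probT_lymphoma": 4,
    "CLBL1": 5,
    "CLBL1M": 5,
    "GL1": 1,
    "OSW": 4,
    "CL1": 2,
    "control": 4,
}

ARCHETYPES = ("all_negative", "all_positive", "near_zero", "cell_line_only", "background")


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults give a desk-scale realistic dataset."""

    # genes per biotype (desk-scale stand-ins for 19,856 / 846 / 8,124)
    n_genes: dict = field(
        default_factory=lambda: {"protein_coding": 2000, "miRNA": 150, "lncRNA": 600}
    )
    replicates: dict = field(default_factory=lambda: dict(DEFAULT_REPLICATES))
    control_group: str = "control"
    # baseline mean: log-normal (meanlog, sdlog); non-coding classes sit lower
    baseline_log_mean: dict = field(
        default_factory=lambda: {
            "protein_coding": (np.log(150.0), 1.3),
            "miRNA": (np.log(15.0), 1.0),
            "lncRNA": (np.log(15.0), 1.0),
        }
    )
    # fraction of annotated genes that are never expressed (mu = 0)
    fraction_undetected: float = 0.10
    # NB dispersion alpha ~ Gamma(shape, scale); mean 0.1
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.05
    # library size factors ~ log-normal around 1
    libsize_sdlog: float = 0.15
    # planted DE structure (gene counts; magnitudes |log2fc| ~ U[0.5, 5])
    n_core_up: int = 40
    n_core_down: int = 40
    n_exclusive_per_group: int = 40
    n_cellline_only: int = 40
    n_discordant: int = 2
    lfc_range: tuple[float, float] = (0.5, 5.0)
    # minimum baseline mean for a gene to be eligible for planting
    min_planted_mean: float = 20.0
    # pathway structure
    n_pathways_per_archetype: dict = field(
        default_factory=lambda: {
            "all_negative": 8,
            "all_positive": 8,
            "near_zero": 8,
            "cell_line_only": 8,
            "background": 28,
        }
    )
    pathway_size_range: tuple[int, int] = (22, 45)
    background_size_range: tuple[int, int] = (10, 60)
    # fraction of an archetype pathway's members taken from its planted pool
    archetype_member_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.replicates.items():
            if n < 1:
                raise ConfigError(f"group {g!r} has replicate count {n}; must be >= 1")
        if not 0.0 <= self.fraction_undetected <= 1.0:
            raise ConfigError("fraction_undetected must be in [0, 1]")
        if self.dispersion_shape <= 0 or self.dispersion_scale <= 0:
            raise ConfigError("dispersion parameters must be > 0")
        if not 0.0 <= self.archetype_member_fraction <= 1.0:
            raise ConfigError("archetype_member_fraction must be in [0, 1]")
        lo, hi = self.lfc_range
        if not 0 < lo <= hi:
            raise ConfigError("lfc_range must satisfy 0 < lo <= hi")
        for bt in self.n_genes:
            if bt not in BIOTYPES:
                raise ConfigError(f"unknown biotype {bt!r}")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the synthetic dataset."""

    beta: pd.DataFrame            # gene x group planted log2 fold changes
    size_factors: pd.Series       # per-sample true s_j
    pathway_archetype: pd.Series  # pathway id -> archetype label
    baseline_mean: pd.Series      # per-gene mu_g
    dispersion: pd.Series         # per-gene alpha_g

    def directions(self) -> pd.DataFrame:
        """Gene x group true direction labels sign(beta)."""
        return np.sign(self.beta).astype(np.int8)


def total_library_count(design: GroupDesign) -> int:
    """Number of RNA-seq libraries in the design (all groups incl. control)."""
    return int(len(design.sample_to_group))


def _make_design(cfg: SimulationConfig) -> GroupDesign:
    samples, groups = [], []
    order = [g for g in cfg.replicates if g != cfg.control_group] + [cfg.control_group]
    for g in order:
        for i in range(cfg.replicates[g]):
            samples.append(f"{g}_{i + 1}")
            groups.append(g)
    return GroupDesign(
        pd.Series(groups, index=samples), control_group=cfg.control_group
    )


def simulate_experiment(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, GroupDesign, GeneSetCollection, SyntheticTruth]:
    """Draw one complete synthetic experiment; identical seed, identical output."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    design = _make_design(cfg)
    de_groups = design.groups  # non-control, canonical order

    # --- genes ------------------------------------------------------------
    gene_ids, biotypes = [], []
    for bt in BIOTYPES:
        n = cfg.n_genes.get(bt, 0)
        gene_ids += [f"{bt[:2].upper()}{i:05d}" for i in range(n)]
        biotypes += [bt] * n
    genes = pd.Index(gene_ids, name="gene_id")
    biotype = pd.Series(biotypes, index=genes)
    n_genes = len(genes)

    mu = np.empty(n_genes)
    for bt in BIOTYPES:
        mask = (biotype == bt).to_numpy()
        meanlog, sdlog = cfg.baseline_log_mean[bt]
        mu[mask] = rng.lognormal(meanlog, sdlog, size=mask.sum())
    undetected = rng.random(n_genes) < cfg.fraction_undetected
    mu[undetected] = 0.0

    alpha = rng.gamma(cfg.dispersion_shape, cfg.dispersion_scale, size=n_genes)

    # --- planted fold changes --------------------------------------------
    beta = pd.DataFrame(0.0, index=genes, columns=de_groups)
    pc = (biotype == "protein_coding").to_numpy()
    eligible = np.flatnonzero(pc & (mu >= cfg.min_planted_mean))
    n_needed = (
        cfg.n_core_up
        + cfg.n_core_down
        + cfg.n_exclusive_per_group * len(de_groups)
        + cfg.n_cellline_only
        + cfg.n_discordant
    )
    if len(eligible) < n_needed:
        raise ConfigError(
            f"only {len(eligible)} well-expressed protein-coding genes but "
            f"{n_needed} planted genes requested"
        )
    chosen = (
        rng.choice(eligible, size=n_needed, replace=False)
        if n_needed
        else np.empty(0, dtype=np.int64)
    )
    pos = 0

    def take(k: int) -> np.ndarray:
        nonlocal pos
        out = chosen[pos : pos + k]
        pos += k
        return out

    lo, hi = cfg.lfc_range
    core_up = take(cfg.n_core_up)
    core_down = take(cfg.n_core_down)
    beta.iloc[core_up] = rng.uniform(lo, hi, size=(len(core_up), 1))
    beta.iloc[core_down] = -rng.uniform(lo, hi, size=(len(core_down), 1))
    exclusive: dict[str, np.ndarray] = {}
    for g in de_groups:
        idx = take(cfg.n_exclusive_per_group)
        exclusive[g] = idx
        mag = rng.uniform(lo, hi, size=len(idx))
        sign = rng.choice([-1.0, 1.0], size=len(idx))
        beta.loc[genes[idx], g] = sign * mag
    cellline_only = take(cfg.n_cellline_only)
    cl_groups = [g for g in de_groups if g in CELL_LINE_GROUPS]
    beta.loc[genes[cellline_only], cl_groups] = -rng.uniform(
        lo, hi, size=(len(cellline_only), 1)
    )
    discordant = take(cfg.n_discordant)
    for idx in discordant:
        mag = rng.uniform(lo, hi)
        beta.iloc[idx] = mag
        if "GL1" in de_groups:
            beta.iloc[idx, beta.columns.get_loc("GL1")] = -mag

    null_pool = np.setdiff1d(eligible, chosen)

    # --- size factors and counts -----------------------------------------
    sf = rng.lognormal(0.0, cfg.libsize_sdlog, size=len(design.sample_to_group))
    sf = pd.Series(sf, index=design.sample_to_group.index, name="size_factor")

    counts = np.zeros((n_genes, len(sf)), dtype=np.int64)
    beta_np = beta.to_numpy()
    col_of = {g: i for i, g in enumerate(de_groups)}
    for j, sample in enumerate(sf.index):
        grp = design.sample_to_group[sample]
        b = beta_np[:, col_of[grp]] if grp in col_of else 0.0
        mean_j = sf.iloc[j] * mu * np.power(2.0, b)
        lam = rng.gamma(1.0 / alpha, alpha * mean_j)
        counts[:, j] = rng.poisson(lam)
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=sf.index), biotype)

    # --- pathways ---------------------------------------------------------
    pools = {
        "all_negative": core_down,
        "all_positive": core_up,
        "cell_line_only": cellline_only,
        "near_zero": null_pool,
    }
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    archetype_labels: dict[str, str] = {}
    p = 0
    for arch in ARCHETYPES:
        for _ in range(cfg.n_pathways_per_archetype.get(arch, 0)):
            pid = f"PW{p:03d}"
            p += 1
            if arch == "background":
                size = int(rng.integers(*cfg.background_size_range, endpoint=True))
                members = rng.choice(n_genes, size=min(size, n_genes), replace=False)
            else:
                size = int(rng.integers(*cfg.pathway_size_range, endpoint=True))
                pool = pools[arch] if arch != "near_zero" else null_pool
                n_from_pool = (
                    size
                    if arch == "near_zero"
                    else max(1, int(round(cfg.archetype_member_fraction * size)))
                )
                n_from_pool = min(n_from_pool, len(pool))
                part1 = rng.choice(pool, size=n_from_pool, replace=False)
                filler_pool = np.setdiff1d(null_pool, part1)
                n_fill = min(size - n_from_pool, len(filler_pool))
                part2 = rng.choice(filler_pool, size=n_fill, replace=False)
                members = np.concatenate([part1, part2])
            sets[pid] = set(genes[members])
            names[pid] = f"{arch} pathway {pid}"
            archetype_labels[pid] = arch
    gsc = GeneSetCollection(sets, names)

    truth = SyntheticTruth(
        beta=beta,
        size_factors=sf,
        pathway_archetype=pd.Series(archetype_labels, name="archetype"),
        baseline_mean=pd.Series(mu, index=genes, name="mu"),
        dispersion=pd.Series(alpha, index=genes, name="alpha"),
    )
    return cm, design, gsc, truth


def simulate_null(
    n_genes: int = 2000,
    replicates: dict | None = None,
    seed: int = 0,
    **overrides,
) -> tuple[CountMatrix, GroupDesign, SyntheticTruth]:
    """Fully null dataset (beta = 0 everywhere) for calibration studies."""
    cfg = SimulationConfig(
        n_genes={"protein_coding": n_genes, "miRNA": 0, "lncRNA": 0},
        replicates=dict(replicates or DEFAULT_REPLICATES),
        fraction_undetected=0.0,
        n_core_up=0,
        n_core_down=0,
        n_exclusive_per_group=0,
        n_cellline_only=0,
        n_discordant=0,
        n_pathways_per_archetype={a: 0 for a in ARCHETYPES},
        seed=seed,
        **overrides,
    )
    # background pathways need >= 1 to build a collection; skip them entirely
    cfg.n_pathways_per_archetype = {a: 0 for a in ARCHETYPES}
    cm, design, _, truth = _simulate_no_pathways(cfg)
    return cm, design, truth


def _simulate_no_pathways(cfg: SimulationConfig):
    """simulate_experiment minus the pathway stage (empty collections are invalid)."""
    cfg2 = SimulationConfig(**{**cfg.__dict__})
    cfg2.n_pathways_per_archetype = {a: (1 if a == "background" else 0) for a in ARCHETYPES}
    cm, design, _, truth = simulate_experiment(cfg2)
    truth.pathway_archetype = truth.pathway_archetype.iloc[0:0]
    return cm, design, None, truth
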