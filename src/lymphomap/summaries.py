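"""Dataset-level summaries: DEG tallies and PCA of DEG expression.

The PCA follows the usual prcomp-style recipe: the sample x gene matrix of
moderated log expression over the DEG union is centered and scaled per gene
(zero-variance genes dropped), decomposed by SVD, and each component's
explained-variance fraction is sigma_i^2 / sum sigma_j^2. For determinism
across linear-algebra backends, every loading vector is oriented so that
its largest-magnitude element is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import log
from .types import ConfigError


@dataclass
class DEGSummary:
    per_group: pd.DataFrame  # n_up, n_down, n_total, frac_abs_log2fc_le_2
    union_all: int


def deg_summary(dirs: pd.DataFrame, results: pd.DataFrame) -> DEGSummary:
    """Per-group up/down/total tallies plus the moderate-fold-change share.

    ``results`` is the long DE table (gene, group, log2fc, ..., call); the
    moderate share is the fraction of a group's called genes with
    |log2fc| <= 2.
    """
    rows = []
    for g in dirs.columns:
        d = dirs[g]
        n_up, n_down = int((d == 1).sum()), int((d == -1).sum())
        called = results[(results["group"] == g) & (results["call"] != "ns")]
        frac = (
            float((called["log2fc"].abs() <= 2).mean()) if len(called) else float("nan")
        )
        rows.append(
            {
                "group": g,
                "n_up": n_up,
                "n_down": n_down,
                "n_total": n_up + n_down,
                "frac_abs_log2fc_le_2": frac,
            }
        )
    union_all = int(((dirs != 0).any(axis=1)).sum())
    return DEGSummary(per_group=pd.DataFrame(rows).set_index("group"), union_all=union_all)


def union_count(dirs: pd.DataFrame, groups) -> int:
    """Number of genes called in at least one of the named groups."""
    missing = [g for g in groups if g not in dirs.columns]
    if missing:
        raise ConfigError(f"unknown group label(s): {missing}")
    return int((dirs[list(groups)] != 0).any(axis=1).sum())


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x k
    variance_fraction: np.ndarray  # length k, non-increasing
    dropped_genes: list[str]


def pca_degs(logexpr: pd.DataFrame, k: int = 2) -> PCAResult:
    """PCA of samples over centered, unit-variance scaled gene rows.

    ``logexpr`` is gene x sample; components are computed on the transposed
    (sample x gene) matrix via SVD.
    """
    if logexpr.shape[1] < 2:
        raise ConfigError("PCA needs at least two samples")
    X = logexpr.to_numpy(dtype=float).T  # samples x genes
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [g for g, k_ in zip(logexpr.index, keep) if not k_]
    if dropped:
        log.info("pca_degs: dropped %d zero-variance genes", len(dropped))
    if keep.sum() < 2:
        raise ConfigError("PCA needs at least two non-constant genes")
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    k = min(k, len(S))
    # orient: largest-|.| loading element positive
    for i in range(k):
        j = int(np.abs(Vt[i]).argmax())
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = pd.DataFrame(
        U[:, :k] * S[:k],
        index=logexpr.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    var_frac = (S**2 / (S**2).sum())[:k]
    return PCAResult(scores=scores, variance_fraction=var_frac, dropped_genes=dropped)
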