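"""Per-group negative-binomial differential expression against controls.

The model for gene *g* in sample *j* of group *G* is

    K_gj ~ NB(mean = s_j * m_gG,  variance = mean + alpha_g * mean^2)

with per-sample size factors ``s_j`` (median-of-ratios), per-group means
``m_gG`` on the log link, and a per-gene dispersion ``alpha_g`` estimated by
method of moments on normalized counts and shrunk toward a fitted
mean-dispersion trend ``a0 + a1/mean``. Each non-control group is compared to
the control group with a Wald test on the log2 fold change

    log2fc = (log m_gG - log m_g,ctrl) / ln 2,

with the standard error from the expected Fisher information of the two
group-mean fits and a two-sided standard-normal p-value. Benjamini-Hochberg
adjustment is applied per contrast, and genes are called up/down at the FDR
cutoff (default 1e-5).

Group means have no shared parameters, so each maximum-likelihood fit is a
one-dimensional root-finding problem solved by Newton iteration on the log
scale, vectorized over genes. A group whose counts are all zero has its mean
floored at half a count per library so the fold change stays finite; the huge
standard error that comes with it makes the Wald test appropriately powerless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import ConfigError, CountMatrix, GroupDesign

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# size factors


def estimate_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For every gene with a nonzero count in all samples, the ratio of each
    sample's count to the gene's geometric mean is formed; a sample's factor
    is the median of its ratios.
    """
    counts = cm.counts.to_numpy(dtype=float)
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "median-of-ratios is undefined (use total-count size factors instead)"
        )
    sub = counts[allpos]
    loggeo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(loggeo)
    sf = np.median(ratios, axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=cm.sample_ids, name="size_factor")


def total_count_size_factors(cm: CountMatrix) -> pd.Series:
    """Column-sum size factors rescaled to geometric mean 1 (simpler fallback)."""
    tot = cm.counts.sum(axis=0).astype(float)
    if (tot <= 0).any():
        raise ValueError("a sample has zero total counts")
    sf = tot / np.exp(np.mean(np.log(tot)))
    sf.name = "size_factor"
    return sf


def moderated_log(cm: CountMatrix, sf: pd.Series, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), a variance-damping transform."""
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be > 0")
    norm = cm.counts.to_numpy(dtype=float) / sf.reindex(cm.sample_ids).to_numpy()
    return pd.DataFrame(np.log2(norm + pseudocount), index=cm.gene_ids, columns=cm.sample_ids)


# ---------------------------------------------------------------------------
# dispersion


def method_of_moments_alpha(
    norm_counts: pd.DataFrame, design: GroupDesign
) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-gene dispersion from pooled within-group moments.

    Using only groups with >= 2 replicates: the within-group variance is
    pooled over groups, the mean is taken over the same samples, and
    ``alpha = max(0, (var - mean) / mean^2)``.

    Returns ``(alpha_raw, mean)`` arrays aligned to ``norm_counts.index``.
    """
    reps = design.replicate_counts()
    multi = [g for g, n in reps.items() if n >= 2]
    if not multi:
        raise ValueError("dispersion estimation needs at least one group with >= 2 replicates")
    ss = np.zeros(norm_counts.shape[0])
    df_total = 0
    used_samples: list[str] = []
    for g in multi:
        samp = design.samples_of(g)
        x = norm_counts[samp].to_numpy(dtype=float)
        ss += ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df_total += len(samp) - 1
        used_samples += samp
    pooled_var = ss / df_total
    mean = norm_counts[used_samples].to_numpy(dtype=float).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mean > 0, (pooled_var - mean) / np.maximum(mean, 1e-300) ** 2, 0.0)
    return np.maximum(alpha, 0.0), mean


def fit_dispersion_trend(alpha_raw: np.ndarray, mean: np.ndarray) -> tuple[float, float]:
    """Non-negative least-squares fit of the trend ``alpha(mu) = a0 + a1/mu``."""
    ok = mean > 0
    A = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, _ = optimize.nnls(A, alpha_raw[ok])
    return float(coef[0]), float(coef[1])


def estimate_dispersion(
    cm: CountMatrix,
    sf: pd.Series,
    design: GroupDesign,
    shrink: float = 0.5,
) -> pd.Series:
    """Per-gene dispersion: method-of-moments shrunk toward the mean trend.

    ``shrink`` is the weight on the fitted trend value (0 = raw per-gene
    estimate, 1 = trend only). Genes in singleton groups contribute no
    within-group information; their contrasts reuse this shared estimate.
    """
    if not 0.0 <= shrink <= 1.0:
        raise ConfigError("shrink weight must be in [0, 1]")
    norm = cm.counts / sf.reindex(cm.sample_ids)
    alpha_raw, mean = method_of_moments_alpha(norm, design)
    a0, a1 = fit_dispersion_trend(alpha_raw, mean)
    with np.errstate(divide="ignore"):
        trend = np.where(mean > 0, a0 + a1 / np.maximum(mean, 1e-300), a0)
    alpha = (1.0 - shrink) * alpha_raw + shrink * trend
    return pd.Series(np.maximum(alpha, 0.0), index=cm.gene_ids, name="alpha")


# ---------------------------------------------------------------------------
# NB group-mean fit and Wald test


def _fit_log_mean(
    y: np.ndarray, s: np.ndarray, alpha: np.ndarray, max_iter: int = 100, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MLE of the per-gene log group mean for an NB with fixed dispersion.

    ``y``: genes x n counts; ``s``: n size factors; ``alpha``: per-gene
    dispersion. Solves sum_j (y_j - s_j m) / (1 + alpha s_j m) = 0 for m by
    Newton iteration in theta = log m (the score is strictly decreasing in m,
    so the root is unique). All-zero genes are floored at half a count
    spread over the group's total size factor.

    Returns ``(theta, info, converged)`` where ``info`` is the expected
    Fisher information sum_j mu_j / (1 + alpha mu_j) at the optimum.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    total = y.sum(axis=1)
    floor = 0.5 / s.sum()
    m0 = np.maximum(total / s.sum(), floor)
    theta = np.log(m0)
    zero = total == 0
    converged = np.zeros(y.shape[0], dtype=bool)
    converged[zero] = True  # floored, nothing to iterate
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        mu = np.exp(theta[active])[:, None] * s[None, :]
        a = alpha[active][:, None]
        denom = 1.0 + a * mu
        score = ((y[active] - mu) / denom).sum(axis=1)
        # d(score)/d(theta); strictly negative
        dscore = -(mu * (1.0 + a * y[active]) / denom**2).sum(axis=1)
        step = score / dscore
        step = np.clip(step, -5.0, 5.0)
        theta[active] = theta[active] - step
        done = np.abs(score) < tol * np.maximum(1.0, total[active])
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
    mu = np.exp(theta)[:, None] * s[None, :]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return theta, info, converged


def wald_test_group(
    counts_g,
    sf: pd.Series,
    design: GroupDesign,
    group: str,
    alpha_g: float,
    max_iter: int = 100,
) -> tuple[float, float, float, float]:
    """Wald test of one gene in ``group`` against the control group.

    Returns ``(log2fc, se, wald, p)``. ``counts_g`` is the gene's per-sample
    count vector (Series indexed by sample id, or alignable mapping).
    """
    if group == design.control_group:
        raise ConfigError("cannot contrast the control group against itself")
    counts_g = pd.Series(counts_g)
    out = wald_test_all(
        counts_g.to_frame().T, sf, design, np.array([alpha_g]), groups=[group], max_iter=max_iter
    )
    row = out.iloc[0]
    return float(row.log2fc), float(row.se), float(row.wald), float(row.p)


def wald_test_all(
    counts: pd.DataFrame,
    sf: pd.Series,
    design: GroupDesign,
    alpha: np.ndarray,
    groups: list[str] | None = None,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Vectorized Wald tests for every gene x every non-control group.

    Returns a long DataFrame with columns
    ``gene, group, log2fc, se, wald, p`` (p is NaN for non-converged fits).
    """
    groups = list(groups) if groups is not None else design.groups
    sf = sf.reindex(counts.columns)
    alpha = np.asarray(alpha, dtype=float)

    ctrl = design.control_samples
    if not ctrl:
        raise ConfigError("control group has no samples")
    th_c, info_c, conv_c = _fit_log_mean(
        counts[ctrl].to_numpy(), sf[ctrl].to_numpy(), alpha, max_iter=max_iter
    )
    frames = []
    for g in groups:
        samp = design.samples_of(g)
        if not samp:
            raise ConfigError(f"group {g!r} has no samples")
        th_g, info_g, conv_g = _fit_log_mean(
            counts[samp].to_numpy(), sf[samp].to_numpy(), alpha, max_iter=max_iter
        )
        log2fc = (th_g - th_c) / LN2
        with np.errstate(divide="ignore"):
            se = np.sqrt(1.0 / info_g + 1.0 / info_c) / LN2
        wald = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
        p = 2.0 * stats.norm.sf(np.abs(wald))
        ok = conv_c & conv_g
        p = np.where(ok, p, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "gene": counts.index,
                    "group": g,
                    "log2fc": log2fc,
                    "se": se,
                    "wald": wald,
                    "p": p,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# multiple testing and calls


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DEResult:
    """Long-format per-gene, per-contrast test results.

    ``table`` columns: gene, group, log2fc, se, wald, p, q, call. Genes whose
    fit did not converge carry ``p = NaN`` and are excluded from that
    contrast's BH vector (call ``ns``).
    """

    table: pd.DataFrame
    fdr: float

    def directions(self) -> pd.DataFrame:
        """Gene x group matrix of direction calls in {+1, -1, 0}."""
        code = self.table["call"].map({"up": 1, "down": -1, "ns": 0}).astype(np.int8)
        wide = self.table.assign(d=code).pivot(index="gene", columns="group", values="d")
        genes = self.table["gene"].drop_duplicates()
        cols = self.table["group"].drop_duplicates()
        return wide.reindex(index=genes, columns=cols).fillna(0).astype(np.int8)


def adjust_and_call(raw: pd.DataFrame, fdr: float = 1e-5) -> DEResult:
    """Apply per-contrast BH adjustment and direction calls to Wald output."""
    parts = []
    for _, sub in raw.groupby("group", sort=False):
        sub = sub.copy()
        q = np.full(len(sub), np.nan)
        ok = sub["p"].notna().to_numpy()
        if ok.any():
            q[ok] = bh_adjust(sub["p"].to_numpy()[ok])
        sub["q"] = q
        parts.append(sub)
    table = pd.concat(parts, ignore_index=True)
    call = np.where(
        (table["q"] <= fdr) & (table["log2fc"] > 0),
        "up",
        np.where((table["q"] <= fdr) & (table["log2fc"] < 0), "down", "ns"),
    )
    call = np.where(table["q"].isna(), "ns", call)
    table["call"] = call
    return DEResult(table=table, fdr=fdr)


def call_directions(result: DEResult, fdr: float | None = None) -> pd.DataFrame:
    """Direction matrix at an FDR cutoff (defaults to the result's own)."""
    if fdr is None:
        return result.directions()
    return adjust_and_call(result.table.drop(columns=["q", "call"]), fdr=fdr).directions()


def run_de(
    cm: CountMatrix,
    design: GroupDesign,
    sf: pd.Series | None = None,
    fdr: float = 1e-5,
    shrink: float = 0.5,
    max_iter: int = 100,
) -> tuple[DEResult, pd.Series, pd.Series]:
    """Full DE stage: size factors, dispersion, Wald tests, BH, calls.

    Returns ``(DEResult, size_factors, dispersions)``.
    """
    if sf is None:
        sf = estimate_size_factors(cm)
    alpha = estimate_dispersion(cm, sf, design, shrink=shrink)
    raw = wald_test_all(cm.counts, sf, design, alpha.to_numpy(), max_iter=max_iter)
    return adjust_and_call(raw, fdr=fdr), sf, alpha
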