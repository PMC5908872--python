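"""Two-stage expression filter: detection, then per-biotype percentile cut.

Stage 1 keeps genes observed with at least one read in at least one library.
Stage 2 removes lowly expressed genes: within each sample, and separately for
each biotype (protein-coding, miRNA, lncRNA), the q-th percentile (default
q = 0.40) of the library-size-normalized counts is computed over that
biotype's genes, and a gene survives iff its normalized count strictly
exceeds the threshold in at least one sample. The percentile uses linear
interpolation between order statistics (numpy's default, "type 7").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import log
from .types import BIOTYPES, ConfigError, CountMatrix, FilterReport


def _biotype_counts(cm: CountMatrix, retained_mask: np.ndarray) -> pd.DataFrame:
    rows = []
    for bt in BIOTYPES:
        in_bt = (cm.biotype == bt).to_numpy()
        rows.append(
            {
                "biotype": bt,
                "n_annotated": int(in_bt.sum()),
                "n_detected": int(in_bt.sum()),
                "n_retained": int((in_bt & retained_mask).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("biotype")


def detection_filter(cm: CountMatrix) -> tuple[CountMatrix, FilterReport]:
    """Keep genes with >= 1 read in >= 1 library; report per-biotype tallies."""
    detected = (cm.counts.to_numpy() > 0).any(axis=1)
    report = _biotype_counts(cm, detected)
    report["n_detected"] = report["n_retained"]
    out = CountMatrix(cm.counts.loc[detected], cm.biotype.loc[detected])
    log.info(
        "detection_filter: %d -> %d genes (%d samples)",
        cm.n_genes, out.n_genes, cm.n_samples,
    )
    return out, FilterReport(counts=report)


def percentile_filter(
    cm: CountMatrix,
    size_factors: pd.Series,
    q: float = 0.40,
) -> tuple[CountMatrix, FilterReport]:
    """Drop genes never strictly above the per-sample, per-biotype percentile.

    ``size_factors`` must be positive; counts are normalized as
    ``count / size_factor`` before thresholding. The percentile population is
    all genes of the same biotype present in the (detection-filtered) input.
    """
    if not 0.0 < q < 1.0:
        raise ConfigError(f"percentile q must be in (0, 1), got {q}")
    sf = size_factors.reindex(cm.sample_ids)
    if sf.isna().any() or (sf <= 0).any():
        raise ConfigError("size factors must be positive and cover every sample")
    norm = cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    retained = np.zeros(cm.n_genes, dtype=bool)
    thresholds = pd.DataFrame(
        np.nan, index=cm.sample_ids, columns=list(BIOTYPES), dtype=float
    )
    for bt in BIOTYPES:
        in_bt = (cm.biotype == bt).to_numpy()
        if not in_bt.any():
            continue
        thr = np.quantile(norm[in_bt], q, axis=0, method="linear")
        thresholds[bt] = thr
        retained[in_bt] = (norm[in_bt] > thr[None, :]).any(axis=1)
    report = _biotype_counts(cm, retained)
    out = CountMatrix(cm.counts.loc[retained], cm.biotype.loc[retained])
    log.info(
        "percentile_filter(q=%.2f): %d -> %d genes", q, cm.n_genes, out.n_genes
    )
    return out, FilterReport(counts=report, thresholds=thresholds, q=q)
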