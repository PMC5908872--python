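"""Pathway "net expression": a signed fraction of dysregulated member genes.

For pathway *p* and sample group *G*,

    NE_pG = (n_up - n_down) / n_detected,

where n_up and n_down count the pathway's significantly up- and
down-regulated genes in the group-vs-control contrast and n_detected is the
number of pathway members in the detected universe (genes with at least one
read in at least one library, BEFORE the low-expression percentile filter).
Pathways with fewer than ``min_size`` (default 20) detected genes are
dropped. Values lie in [-1, 1]; bands: near_zero (|v| <= 0.05),
negative (v < -0.10), positive (v > 0.10), weak (in between).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import log
from .types import ConfigError, CountMatrix, GeneSetCollection

BAND_NEAR_ZERO = "near_zero"
BAND_WEAK = "weak"
BAND_NEGATIVE = "negative"
BAND_POSITIVE = "positive"


def detected_universe(counts_raw: CountMatrix) -> set[str]:
    """Genes with >= 1 read in >= 1 library of the raw (unfiltered) matrix."""
    mask = (counts_raw.counts.to_numpy() > 0).any(axis=1)
    return set(counts_raw.counts.index[mask])


def net_expression(n_up: int, n_down: int, n_detected: int) -> float:
    """(n_up - n_down) / n_detected."""
    if n_detected <= 0:
        raise ConfigError("pathway with no detected genes cannot be scored")
    if n_up + n_down > n_detected:
        raise ConfigError("n_up + n_down exceeds n_detected")
    return (n_up - n_down) / n_detected


def classify_band(value: float) -> str:
    """Band label for a net-expression value in [-1, 1]."""
    if abs(value) <= 0.05:
        return BAND_NEAR_ZERO
    if value < -0.10:
        return BAND_NEGATIVE
    if value > 0.10:
        return BAND_POSITIVE
    return BAND_WEAK


@dataclass
class NetExpressionMatrix:
    """Pathway x group net expression with the counts it derives from."""

    ne: pd.DataFrame        # pathway x group, float in [-1, 1]
    n_up: pd.DataFrame      # pathway x group, int
    n_down: pd.DataFrame    # pathway x group, int
    n_detected: pd.Series   # per pathway, int

    def bands(self) -> pd.DataFrame:
        return self.ne.map(classify_band)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for p in self.ne.index:
            for g in self.ne.columns:
                v = self.ne.loc[p, g]
                rows.append(
                    {
                        "pathway": p,
                        "group": g,
                        "n_up": int(self.n_up.loc[p, g]),
                        "n_down": int(self.n_down.loc[p, g]),
                        "n_detected": int(self.n_detected.loc[p]),
                        "NE": v,
                        "band": classify_band(v),
                    }
                )
        return pd.DataFrame(rows)


def net_expression_matrix(
    dirs: pd.DataFrame,
    sets: GeneSetCollection,
    universe: set[str],
    min_size: int = 20,
) -> NetExpressionMatrix:
    """Score every sufficiently detected pathway in every group.

    Pathway membership is intersected with the detected universe; genes of
    the universe absent from ``dirs`` (e.g. removed by the low-expression
    filter) count as not called. Pathways with fewer than ``min_size``
    detected members are dropped (logged).
    """
    groups = list(dirs.columns)
    kept, dropped = [], []
    detected_members: dict[str, list[str]] = {}
    for sid in sets.ids():
        members = sorted(sets[sid] & universe)
        if len(members) >= min_size:
            kept.append(sid)
            detected_members[sid] = members
        else:
            dropped.append(sid)
    if not kept:
        raise ConfigError(
            f"no pathway has >= {min_size} detected genes; nothing to score"
        )
    if dropped:
        log.info(
            "net_expression_matrix: dropped %d/%d pathways below %d detected genes",
            len(dropped), len(sets), min_size,
        )
    n_up = pd.DataFrame(0, index=kept, columns=groups, dtype=int)
    n_down = pd.DataFrame(0, index=kept, columns=groups, dtype=int)
    n_det = pd.Series({sid: len(detected_members[sid]) for sid in kept}, dtype=int)
    for sid in kept:
        present = dirs.index.intersection(detected_members[sid])
        sub = dirs.loc[present]
        n_up.loc[sid] = (sub == 1).sum(axis=0)
        n_down.loc[sid] = (sub == -1).sum(axis=0)
    ne = (n_up - n_down).div(n_det, axis=0).astype(float)
    return NetExpressionMatrix(ne=ne, n_up=n_up, n_down=n_down, n_detected=n_det)
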