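"""Readers and writers for the pipeline's external formats.

Everything tabular is tab-separated UTF-8 with '.' decimals, matching the
dialect of GEO-style supplementary matrices. Gene ids are opaque strings.
Real-valued tables are written with enough digits (%.12g) that a
write-then-read round trip is exact to >= 12 significant figures.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CountMatrix, FormatError, GeneSetCollection, GroupDesign

log = logging.getLogger("lymphomap")

FLOAT_FMT = "%.17g"


def setup_logging(level: int = logging.INFO) -> None:
    """One stderr line per stage: dimensions in/out and active thresholds."""
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(name)s: %(message)s"))
        log.addHandler(h)
    log.setLevel(level)


# ---------------------------------------------------------------------------
# count matrix


def read_count_matrix(path) -> CountMatrix:
    """Read a gene x sample TSV of integer counts.

    First column: gene id; optional second column named ``biotype``
    (missing -> every gene is ``protein_coding``); remaining columns: samples.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no samples (empty file)") from None
    if df.shape[1] == 0 or (df.shape[1] == 1 and df.columns[0] == "biotype"):
        raise FormatError(f"{path}: no samples")
    if df.columns[0] == "biotype":
        biotype = df.iloc[:, 0]
        df = df.iloc[:, 1:]
    else:
        biotype = pd.Series("protein_coding", index=df.index)
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() | (num.astype(float) % 1 != 0)
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise FormatError(
                f"{path}: non-integer count {df[col].iloc[i]!r} at gene "
                f"{df.index[i]!r}, sample {col!r}"
            )
        if (num < 0).any():
            i = int(np.argmax((num < 0).to_numpy()))
            raise FormatError(
                f"{path}: negative count {df[col].iloc[i]!r} at gene "
                f"{df.index[i]!r}, sample {col!r}"
            )
        values[:, j] = num.astype(np.int64)
    counts = pd.DataFrame(values, index=df.index, columns=df.columns)
    counts.index.name = "gene_id"
    return CountMatrix(counts, biotype)


def write_count_matrix(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.insert(0, "biotype", cm.biotype)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample sheet


def read_sample_sheet(path, control_group: str = "control") -> GroupDesign:
    """Read a two-column TSV (sample, group) into a :class:`GroupDesign`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: sample sheet is missing column {col!r}")
    s = pd.Series(df["group"].to_numpy(), index=df["sample"].to_numpy())
    return GroupDesign(s, control_group=control_group)


def write_sample_sheet(design: GroupDesign, path) -> None:
    df = pd.DataFrame(
        {"sample": design.sample_to_group.index, "group": design.sample_to_group.values}
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``set_id TAB description TAB member...`` per line.

    Duplicate members within a set are dropped; a line with fewer than three
    fields is a format error reported with its line number.
    """
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            sid, desc = fields[0], fields[1]
            if sid in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set id {sid!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {sid!r} has no members")
            sets[sid] = members
            names[sid] = desc
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetCollection(sets, names)


def write_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid in gsc.ids():
            desc = gsc.names.get(sid, sid)
            fh.write("\t".join([sid, desc, *sorted(gsc.sets[sid])]) + "\n")


# ---------------------------------------------------------------------------
# real-valued tables


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
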