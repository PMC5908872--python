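"""Core domain containers shared by every pipeline stage.

All tabular data is carried in pandas objects; the dataclasses here add the
domain invariants (integer non-negative counts, unique identifiers, one
biotype per gene, one group per sample) on top of them and validate on
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIOTYPES = ("protein_coding", "miRNA", "lncRNA")

#: Canonical ordering of the seven disease/cell-line groups compared against
#: the non-neoplastic controls.
GROUP_ORDER = ("B_lymphoma", "probT_lymphoma", "CLBL1", "CLBL1M", "GL1", "OSW", "CL1")

#: Groups that are cultured cell lines (as opposed to primary lymphoma samples).
CELL_LINE_GROUPS = ("CLBL1", "CLBL1M", "GL1", "OSW", "CL1")


class FormatError(ValueError):
    """A file or table violates the expected dialect."""


class ConfigError(ValueError):
    """An invalid configuration value."""


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample; integer dtype.
    biotype
        Per-gene class label, one of :data:`BIOTYPES`, aligned to ``counts.index``.
    """

    counts: pd.DataFrame
    biotype: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if not np.issubdtype(self.counts.to_numpy().dtype, np.integer):
            raise FormatError("counts must be integers")
        if (self.counts.to_numpy() < 0).any():
            g, s = np.argwhere(self.counts.to_numpy() < 0)[0]
            raise FormatError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        self.biotype = self.biotype.reindex(self.counts.index).rename("biotype")
        if self.biotype.isna().any():
            missing = self.biotype.index[self.biotype.isna()][0]
            raise FormatError(f"gene {missing!r} has no biotype label")
        bad = set(self.biotype.unique()) - set(BIOTYPES)
        if bad:
            raise FormatError(f"unknown biotype label(s): {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes) -> "CountMatrix":
        """Return a new matrix restricted to ``genes`` (order preserved)."""
        idx = self.counts.index.intersection(pd.Index(genes), sort=False)
        return CountMatrix(self.counts.loc[idx], self.biotype.loc[idx])


@dataclass
class GroupDesign:
    """Sample -> group assignment with one designated control group."""

    sample_to_group: pd.Series
    control_group: str = "control"
    group_order: tuple[str, ...] = GROUP_ORDER
    #: set False to allow degenerate designs (no / single control) in tests
    validate: bool = True

    def __post_init__(self) -> None:
        self.sample_to_group = pd.Series(self.sample_to_group, dtype=object)
        if self.sample_to_group.index.has_duplicates:
            dup = self.sample_to_group.index[self.sample_to_group.index.duplicated()][0]
            raise FormatError(f"sample {dup!r} assigned more than once")
        if self.validate:
            n_ctrl = int((self.sample_to_group == self.control_group).sum())
            if n_ctrl == 0:
                raise ConfigError(f"control group {self.control_group!r} has no samples")
            if n_ctrl < 2:
                raise ConfigError(
                    f"control group {self.control_group!r} needs >= 2 samples for "
                    "variance estimation (pass validate=False to override)"
                )

    @property
    def groups(self) -> list[str]:
        """Non-control groups, canonical order first, extras appended sorted."""
        present = set(self.sample_to_group.values) - {self.control_group}
        ordered = [g for g in self.group_order if g in present]
        ordered += sorted(present - set(ordered))
        return ordered

    def samples_of(self, group: str) -> list[str]:
        return list(self.sample_to_group.index[self.sample_to_group == group])

    @property
    def control_samples(self) -> list[str]:
        return self.samples_of(self.control_group)

    def replicate_counts(self) -> pd.Series:
        return self.sample_to_group.value_counts()


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathways); members are de-duplicated on load."""

    sets: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {sid!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, sid: str) -> set[str]:
        return self.sets[sid]

    def ids(self) -> list[str]:
        return list(self.sets)


@dataclass
class FilterReport:
    """Per-biotype bookkeeping of a filter step.

    ``counts`` has one row per biotype with columns ``n_annotated`` (genes
    entering the step), ``n_detected`` and ``n_retained``; ``thresholds``
    (percentile step only) holds the per-sample, per-biotype cutoff on the
    normalized-count scale.
    """

    counts: pd.DataFrame
    thresholds: pd.DataFrame | None = None
    q: float | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if not ((c["n_retained"] <= c["n_detected"]).all()
                and (c["n_detected"] <= c["n_annotated"]).all()):
            raise ValueError("filter report violates n_retained <= n_detected <= n_annotated")
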