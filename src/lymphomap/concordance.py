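"""Multi-group set algebra on direction calls.

Given the gene x group direction matrix (+1 up, -1 down, 0 not significant),
this module partitions called genes by the exact combination of groups
calling them (Venn cells, separately for up and for down calls), classifies
genes called in a reference group by their consistency across comparison
groups ("unchanged" means no call, d = 0), and extracts the all-group core:
genes called in every group, split into concordant-up, concordant-down and
discordant (mixed-sign) sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .types import ConfigError

NOT_CALLED = "not_called"
CONCORDANT_UP = "concordant_up"
CONCORDANT_DOWN = "concordant_down"
DISCORDANT = "discordant"


def _check_groups(dirs: pd.DataFrame, groups) -> list[str]:
    groups = list(groups)
    unknown = [g for g in groups if g not in dirs.columns]
    if unknown:
        raise ConfigError(f"unknown group label(s): {unknown}")
    return groups


def venn_partition(
    dirs: pd.DataFrame, groups
) -> dict[str, dict[frozenset, set[str]]]:
    """Partition called genes by the exact combination of calling groups.

    Returns ``{"up": {combo: genes}, "down": {combo: genes}}`` where ``combo``
    is a frozenset of group labels and every gene called in >= 1 of the
    selected groups lands in exactly one cell of the matching direction.
    """
    groups = _check_groups(dirs, groups)
    if len(groups) < 2:
        raise ConfigError("venn partition needs at least two groups")
    out: dict[str, dict[frozenset, set[str]]] = {"up": {}, "down": {}}
    sub = dirs[groups]
    for direction, d in (("up", 1), ("down", -1)):
        mask = sub == d
        for gene, row in mask.iterrows():
            combo = frozenset(g for g in groups if row[g])
            if combo:
                out[direction].setdefault(combo, set()).add(gene)
    return out


def consistency_class(
    dirs: pd.DataFrame, reference_group: str, comparison_groups
) -> pd.Series:
    """Classify each gene called in the reference group against comparisons.

    concordant_up: reference up and every comparison in {up, unchanged};
    concordant_down: the mirror image; discordant otherwise. Genes not called
    in the reference group are labelled not_called.
    """
    comparison_groups = _check_groups(dirs, comparison_groups)
    _check_groups(dirs, [reference_group])
    ref = dirs[reference_group]
    comp = dirs[comparison_groups]
    up_ok = (comp >= 0).all(axis=1)
    down_ok = (comp <= 0).all(axis=1)
    cls = pd.Series(NOT_CALLED, index=dirs.index, dtype=object)
    cls[(ref == 1) & up_ok] = CONCORDANT_UP
    cls[(ref == 1) & ~up_ok] = DISCORDANT
    cls[(ref == -1) & down_ok] = CONCORDANT_DOWN
    cls[(ref == -1) & ~down_ok] = DISCORDANT
    return cls


def all_group_core(dirs: pd.DataFrame) -> tuple[set[str], set[str], set[str]]:
    """Genes called in EVERY group, split by direction agreement.

    Returns ``(concordant_up, concordant_down, discordant)``; the three sets
    are disjoint and their union is the core.
    """
    if dirs.shape[1] < 2:
        raise ConfigError("all-group core needs at least two groups")
    called_everywhere = (dirs != 0).all(axis=1)
    core = dirs.loc[called_everywhere]
    up = set(core.index[(core == 1).all(axis=1)])
    down = set(core.index[(core == -1).all(axis=1)])
    disc = set(core.index) - up - down
    return up, down, disc


@dataclass
class ConcordanceTable:
    """Per-gene concordance annotation over a set of groups."""

    table: pd.DataFrame  # direction columns + partition_up/partition_down/class

    @classmethod
    def build(cls, dirs: pd.DataFrame, reference_group: str, comparison_groups):
        comparison_groups = _check_groups(dirs, comparison_groups)
        groups = [reference_group] + comparison_groups
        part = venn_partition(dirs, groups)
        label_up = pd.Series("", index=dirs.index, dtype=object)
        label_down = pd.Series("", index=dirs.index, dtype=object)
        for combo, genes in part["up"].items():
            label_up.loc[list(genes)] = "&".join(sorted(combo))
        for combo, genes in part["down"].items():
            label_down.loc[list(genes)] = "&".join(sorted(combo))
        table = dirs[groups].copy()
        table["partition_up"] = label_up
        table["partition_down"] = label_down
        table["class"] = consistency_class(dirs, reference_group, comparison_groups)
        return cls(table=table)


def reference_percentages(
    dirs: pd.DataFrame, reference_group: str, comparison_groups
) -> pd.DataFrame:
    """Shares of reference-called genes also called (same sign) in ALL comparisons.

    Denominators are the reference group's up- and down-called gene counts,
    e.g. "19% of the genes up-regulated in B-cell lymphomas were up-regulated
    in all B-cell-derived cell lines".
    """
    comparison_groups = _check_groups(dirs, comparison_groups)
    ref = dirs[reference_group]
    comp = dirs[comparison_groups]
    rows = []
    for direction, d in (("up", 1), ("down", -1)):
        in_ref = ref == d
        in_all = in_ref & (comp == d).all(axis=1)
        n_ref = int(in_ref.sum())
        rows.append(
            {
                "direction": direction,
                "n_reference": n_ref,
                "n_in_all_comparisons": int(in_all.sum()),
                "percent": 100.0 * in_all.sum() / n_ref if n_ref else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("direction")
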