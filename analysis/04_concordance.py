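"""Direction concordance across groups.

Builds the all-group core (uniform-sign vs. discordant genes), the
lymphoma-vs-cell-line consistency classes, and reference-share percentages;
compares the recovered core against the planted truth.
"""

import sys
from pathlib import Path

import pandas as pd

from lymphomap import concordance
from lymphomap.io import read_table, setup_logging, write_table
from lymphomap.types import CELL_LINE_GROUPS

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    setup_logging()
    dirs = read_table(ROOT / "de" / "directions.tsv").astype("int8")
    truth_beta = read_table(ROOT / "data" / "truth_beta.tsv")

    up, down, disc = concordance.all_group_core(dirs)
    cell_lines = [g for g in dirs.columns if g in CELL_LINE_GROUPS]
    table = concordance.ConcordanceTable.build(dirs, "B_lymphoma", cell_lines)
    shares = concordance.reference_percentages(dirs, "B_lymphoma", cell_lines)

    out = ROOT / "concordance"
    out.mkdir(parents=True, exist_ok=True)
    write_table(table.table, out / "b_lymphoma_vs_cell_lines.tsv")
    write_table(shares, out / "b_lymphoma_shares.tsv")
    core = pd.DataFrame(
        {"gene": sorted(up) + sorted(down) + sorted(disc),
         "core_class": ["concordant_up"] * len(up)
         + ["concordant_down"] * len(down)
         + ["discordant"] * len(disc)}
    )
    write_table(core, out / "all_group_core.tsv", index=False)

    true_up = set(truth_beta.index[(truth_beta > 0).all(axis=1)])
    true_down = set(truth_beta.index[(truth_beta < 0).all(axis=1)])
    print(
        f"all-group core: {len(up)} up + {len(down)} down + {len(disc)} discordant "
        f"= {len(up) + len(down) + len(disc)} genes"
    )
    print(
        f"planted core recovered: {len(up & true_up)}/{len(true_up)} up, "
        f"{len(down & true_down)}/{len(true_down)} down"
    )
    print(shares.to_string())


if __name__ == "__main__":
    sys.exit(main())
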