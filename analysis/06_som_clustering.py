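"""SOM clustering of pathway net-expression profiles.

Trains the 4x4 hexagonal map on the pathway x group net-expression matrix,
assigns each pathway to its best-matching unit, labels units by the band of
their median net expression, and reports how the planted archetypes spread
over the grid.
"""

import json
import sys
from pathlib import Path

from lymphomap import som
from lymphomap.io import read_table, setup_logging, write_table

SEED = 7
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    setup_logging()
    ne = read_table(ROOT / "pathways" / "net_expression_matrix.tsv")
    archetypes = read_table(ROOT / "data" / "truth_archetypes.tsv")["archetype"]

    model = som.train_som(ne, rows=4, cols=4, epochs=100, seed=SEED)
    assignment = som.assign_bmu(model, ne)
    out = ROOT / "som"
    out.mkdir(parents=True, exist_ok=True)
    table = assignment.units.to_frame()
    table["unit_band"] = assignment.summary["band"].reindex(assignment.units).to_numpy()
    table["archetype"] = archetypes.reindex(table.index).fillna("background")
    table.index.name = "pathway"
    write_table(table, out / "som_assignment.tsv")
    write_table(assignment.summary, out / "som_units.tsv")
    (out / "som_model.json").write_text(
        json.dumps(model.to_dict(), indent=1, sort_keys=True)
    )

    bands = assignment.summary.loc[assignment.summary["n_pathways"] > 0, "band"]
    counts = assignment.summary["n_pathways"]
    per_band = {
        b: int(counts[bands.index[bands == b]].sum()) for b in sorted(bands.unique())
    }
    print(
        f"quantization error {model.qe_per_epoch[0]:.3f} -> "
        f"{model.qe_per_epoch[-1]:.3f} over {len(model.qe_per_epoch)} epochs"
    )
    print(f"pathways per unit band: {per_band} (of {int(counts.sum())} pathways)")
    for arch in ("all_negative", "all_positive", "near_zero", "cell_line_only"):
        members = table.index[table["archetype"] == arch]
        units = sorted(set(table.loc[members, "unit"]))
        print(f"  {arch}: units {units}")


if __name__ == "__main__":
    sys.exit(main())
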