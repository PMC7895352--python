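#!/usr/bin/env python
"""Cross-comparison summary of the DE call sets: Venn region counts with
direction concordance, the union set, and hierarchical-clustering order of
the union-set expression matrix (the clustered-heatmap skeleton).

Reads results/calls_*.tsv + filtered.tsv; writes venn_summary.tsv,
union_features.txt, cluster_order.json (and heatmap.png if matplotlib is
available).
"""

import json
from pathlib import Path

import pandas as pd

import retrostress as rs

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    call_files = sorted(BASE.glob("calls_*.tsv"))
    call_sets = {}
    for f in call_files:
        label = f.stem.removeprefix("calls_")
        df = pd.read_csv(f, sep="\t", index_col="feature")
        call_sets[label] = dict(zip(df.index, df["direction"]))
    labels = list(call_sets)

    if len(labels) == 2:
        v = rs.venn(call_sets[labels[0]], call_sets[labels[1]], *labels)
        pd.DataFrame(
            [
                {
                    "only_" + labels[0]: v.only_a,
                    "only_" + labels[1]: v.only_b,
                    "shared": v.intersection,
                    "concordant": v.concordant,
                    "discordant": v.discordant,
                }
            ]
        ).to_csv(BASE / "venn_summary.tsv", sep="\t", index=False)
        print(f"venn: {v.only_a} only-{labels[0]}, {v.only_b} only-{labels[1]}, "
              f"{v.intersection} shared ({v.concordant} concordant in direction)")

    union = rs.union_set(*[list(cs) for cs in call_sets.values()])
    (BASE / "union_features.txt").write_text("\n".join(union) + "\n")
    print(f"union set: {len(union)} features")

    if len(union) >= 2:
        filtered = pd.read_csv(BASE / "filtered.tsv", sep="\t", index_col="feature")
        order = rs.cluster_heatmap_order(filtered.loc[union])
        (BASE / "cluster_order.json").write_text(
            json.dumps(
                {
                    "feature_order": order.feature_order,
                    "sample_order": order.sample_order,
                    "metric": order.metric,
                    "method": order.method,
                },
                indent=2,
            )
        )
        print(f"clustered ({order.metric}/{order.method}); "
              f"sample order: {order.sample_order}")
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            mat = filtered.loc[order.feature_order, order.sample_order]
            fig, ax = plt.subplots(figsize=(6, 8))
            im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r")
            ax.set_xticks(range(len(mat.columns)))
            ax.set_xticklabels(mat.columns, rotation=90, fontsize=6)
            ax.set_yticks([])
            fig.colorbar(im, label="normalized log2 expression")
            fig.tight_layout()
            fig.savefig(BASE / "heatmap.png", dpi=120)
            print(f"wrote {BASE / 'heatmap.png'}")
        except ImportError:
            print("matplotlib unavailable; skipped heatmap rendering")
    else:
        print("union set too small to cluster")


if __name__ == "__main__":
    main()
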