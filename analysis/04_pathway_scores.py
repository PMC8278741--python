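#!/usr/bin/env python
"""Score enriched pathways: imbalance A, permutation-null degree score DS.

Each enriched set is split into up/down members by differential direction,
weighted by co-expression, scored per sample against the inactivated-group
reference means, and standardized against 1000 random same-shape gene sets
drawn from the immune pool. The activated-vs-inactivated contrast of DS is
reported per pathway.
"""

from pathlib import Path

import pandas as pd

from hgfmet import group_compare
from hgfmet import io as hio
from hgfmet.activation import ActivationLabels
from hgfmet.pipeline import _child_seed, build_pathways
from hgfmet.pathway import score_pathway

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20260104 % (2**31)


def main() -> None:
    meta = hio.read_metadata_tsv(BASE / "data" / "metadata.tsv")
    expr = hio.read_expression_tsv(BASE / "data" / "expression.tsv", sample_meta=meta)
    labels = ActivationLabels(
        table=pd.read_csv(BASE / "activation.tsv", sep="\t", index_col=0),
        pearson_r=float("nan"), pearson_p=float("nan"),
    )
    degs = pd.read_csv(BASE / "degs.tsv", sep="\t", index_col=0)
    enr = pd.read_csv(BASE / "enrichment.tsv", sep="\t", index_col=0)
    sets = hio.read_gmt(BASE / "data" / "gene_sets.gmt")
    immune = hio.read_gene_list(BASE / "data" / "immune_genes.txt")

    up = frozenset(degs.index[degs["direction"] == "up"])
    down = frozenset(degs.index[degs["direction"] == "down"])
    pathways = build_pathways(enr, sets, up, down)
    pool = sorted(g for g in immune if g in expr.gene_ids)
    log2x = expr.log2_values()

    ds_rows, a_rows, summary = {}, {}, []
    for i, pw in enumerate(pathways):
        res = score_pathway(log2x, pw, pool, labels.inactivated_samples,
                            n_perm=1000, seed=_child_seed(SEED, 100 + i))
        t, p, direction = group_compare(res.DS, labels)
        ds_rows[pw.name], a_rows[pw.name] = res.DS, res.A
        summary.append((pw.name, len(pw.up_genes), len(pw.down_genes), t, p, direction))

    pd.DataFrame(a_rows).T.to_csv(BASE / "pathway_A.tsv", sep="\t",
                                  index_label="pathway")
    pd.DataFrame(ds_rows).T.to_csv(BASE / "pathway_DS.tsv", sep="\t",
                                   index_label="pathway")
    table = pd.DataFrame(
        summary, columns=["pathway", "n_up", "n_down", "t", "p_value", "direction"]
    ).set_index("pathway").sort_values("p_value")
    table.to_csv(BASE / "pathway_summary.tsv", sep="\t")
    print(f"scored {len(pathways)} pathways "
          f"(of {len(enr)} enriched sets; the rest lack an up or down member)")
    print(table)


if __name__ == "__main__":
    main()
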