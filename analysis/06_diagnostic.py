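#!/usr/bin/env python
"""Train and evaluate the tumor-vs-normal diagnostic classifier.

Features: cell fractions + degree scores of the top pathways + log2 HGF and
log2 MET. A 16-unit single-hidden-layer network is assessed by stratified
5-fold cross-validation; out-of-fold probabilities are pooled into one ROC.
"""

import json
from pathlib import Path

import pandas as pd

from hgfmet import assemble_features, train_classifier_cv
from hgfmet import io as hio
from hgfmet.activation import ActivationLabels
from hgfmet.infiltration import InfiltrationFractions
from hgfmet.pipeline import _child_seed, build_pathways
from hgfmet.pathway import score_pathway

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20260106 % (2**31)


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
    frac_table = pd.read_csv(BASE / "fractions.tsv", sep="\t", index_col=0)

    fractions = InfiltrationFractions(
        fractions=frac_table.drop(columns=["abundance", "residual"]),
        abundance=frac_table["abundance"],
        residual=frac_table["residual"],
        degenerate=pd.Series(False, index=frac_table.index),
    )
    up = frozenset(degs.index[degs["direction"] == "up"])
    down = frozenset(degs.index[degs["direction"] == "down"])
    pathways = build_pathways(enr, sets, up, down)
    pool = sorted(g for g in immune if g in expr.gene_ids)
    log2x = expr.log2_values()
    scores, pvalues = [], {}
    for i, pw in enumerate(pathways):
        res = score_pathway(log2x, pw, pool, labels.inactivated_samples,
                            n_perm=1000, seed=_child_seed(SEED, 100 + i))
        scores.append(res)
        from hgfmet import group_compare
        pvalues[pw.name] = group_compare(res.DS, labels)[1]

    features = assemble_features(scores, pvalues, fractions, expr)
    roc = train_classifier_cv(features, k_folds=5, seed=_child_seed(SEED, 200))

    features.X.to_csv(BASE / "features.tsv", sep="\t", index_label="sample_id")
    roc.predictions.to_csv(BASE / "predictions.tsv", sep="\t",
                           index_label="sample_id")
    roc.curve().to_csv(BASE / "roc.tsv", sep="\t", index=False)
    (BASE / "metrics.json").write_text(json.dumps(
        {"auc": roc.auc, "accuracy": roc.accuracy,
         "n_features": features.X.shape[1], "k_folds": 5, "seed": SEED},
        indent=1))
    print(f"{features.X.shape[1]} features over {features.X.shape[0]} samples "
          f"({int(features.y.sum())} tumors, {int((1 - features.y).sum())} normals)")
    print(f"pooled cross-validated AUC = {roc.auc:.3f}, "
          f"accuracy at 0.5 = {roc.accuracy:.3f}")


if __name__ == "__main__":
    main()
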