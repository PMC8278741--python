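"""End-to-end orchestration of the analysis stages.

Stage order mirrors the analysis this package implements: activation
labelling -> immune-gene differential screen -> over-representation
analysis -> pathway imbalance/degree scoring -> immune deconvolution and
gene correlations -> diagnostic classifier -> survival comparison. All
randomness flows from one seed fanned out into per-stage child seeds, so a
config + seed pair fully determines every output file.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .activation import ActivationLabels, classify_activation
from .containers import ExpressionMatrix, GeneSetCollection, SignatureMatrix, PURITY_COL
from .diagnostic import FeatureTable, ROCResult, assemble_features, train_classifier_cv
from .diffexpr import screen_degs, split_by_direction
from .enrichment import enrich
from .errors import InputError
from .infiltration import InfiltrationFractions, correlate_with_gene, deconvolve
from .pathway import (
    PathwayDefinition,
    PathwayScoreResult,
    group_compare,
    score_pathway,
)
from .survival import feature_logrank_table, km_curves

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    hgf_id: str = "HGF"
    met_id: str = "MET"
    ratio_lo: float = 0.5
    ratio_hi: float = 1.5
    per_cancer_scaling: bool = False
    alpha: float = 0.05
    adjust: str = "none"
    min_overlap: int = 2
    top_n_sets: int = 20
    n_perm: int = 1000
    reference: str = "inactivated"  # or "normal"
    top_k_pathways: int = 20
    k_folds: int = 5
    seed: int = 0


@dataclass
class PipelineResult:
    activation: ActivationLabels
    degs: pd.DataFrame
    enrichment: pd.DataFrame
    pathways: list[PathwayDefinition]
    scores: list[PathwayScoreResult]
    pathway_summary: pd.DataFrame
    fractions: InfiltrationFractions
    correlations: pd.DataFrame
    features: FeatureTable
    roc: ROCResult
    survival_logrank: pd.DataFrame | None = None
    km: pd.DataFrame | None = None


def _child_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def build_pathways(
    enrichment_table: pd.DataFrame,
    collection: GeneSetCollection,
    up_degs: frozenset[str],
    down_degs: frozenset[str],
) -> list[PathwayDefinition]:
    """Split each enriched set into up/down members by DEG direction.

    Sets lacking an up or a down differential member are unscoreable and
    skipped (logged).
    """
    pathways = []
    for name in enrichment_table.index:
        genes = collection[name]
        up = tuple(sorted(genes & up_degs))
        down = tuple(sorted(genes & down_degs))
        if not up or not down:
            logger.info("set %s unscoreable (up=%d, down=%d)", name, len(up), len(down))
            continue
        pathways.append(PathwayDefinition(name=name, up_genes=up, down_genes=down))
    return pathways


def analyze(
    expr: ExpressionMatrix,
    immune_genes: list[str],
    gene_sets: GeneSetCollection,
    signature: SignatureMatrix,
    survival: pd.DataFrame | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs; see module docstring for order."""
    p = params or PipelineParams()
    t0 = time.perf_counter()

    labels = classify_activation(
        expr, p.hgf_id, p.met_id, p.ratio_lo, p.ratio_hi, p.per_cancer_scaling
    )
    logger.info(
        "activation: %d activated / %d inactivated (r=%.3f) [%.1fs]",
        len(labels.activated_samples), len(labels.inactivated_samples),
        labels.pearson_r, time.perf_counter() - t0,
    )

    degs = screen_degs(expr, labels, immune_genes, alpha=p.alpha, adjust=p.adjust)
    up_degs, down_degs = split_by_direction(degs)
    logger.info("degs: %d up / %d down of %d immune genes",
                len(up_degs), len(down_degs), len(immune_genes))

    universe = frozenset(g for g in immune_genes if g in expr.gene_ids)
    enr = enrich(frozenset(degs.index), gene_sets, universe,
                 min_overlap=p.min_overlap, top_n=p.top_n_sets)
    logger.info("enrichment: %d sets reported", len(enr))

    pathways = build_pathways(enr, gene_sets, up_degs, down_degs)
    if p.reference == "inactivated":
        reference_samples = labels.inactivated_samples
    elif p.reference == "normal":
        reference_samples = expr.normal_samples
    else:
        raise InputError(f"unknown reference group '{p.reference}'")
    if len(reference_samples) == 0:
        raise InputError(f"reference group '{p.reference}' is empty")

    log2x = expr.log2_values()
    pool = sorted(universe)
    scores: list[PathwayScoreResult] = []
    summary_rows = []
    for i, pw in enumerate(pathways):
        res = score_pathway(
            log2x, pw, pool, reference_samples,
            n_perm=p.n_perm, seed=_child_seed(p.seed, 100 + i),
        )
        t, pval, direction = group_compare(res.DS, labels)
        scores.append(res)
        summary_rows.append((pw.name, len(pw.up_genes), len(pw.down_genes),
                             t, pval, direction))
    pathway_summary = pd.DataFrame(
        summary_rows,
        columns=["pathway", "n_up", "n_down", "t", "p_value", "direction"],
    ).set_index("pathway").sort_values("p_value", kind="mergesort")
    logger.info("pathway scores: %d scoreable pathways", len(scores))

    fractions = deconvolve(expr, signature)
    purity = expr.sample_meta[PURITY_COL] if PURITY_COL in expr.sample_meta else None
    tumor_ids = expr.tumor_samples
    corr_frames = []
    for gid in (p.hgf_id, p.met_id):
        gexpr = expr.values.loc[gid, tumor_ids]
        tumor_frac = InfiltrationFractions(
            fractions=fractions.fractions.loc[tumor_ids],
            abundance=fractions.abundance.loc[tumor_ids],
            residual=fractions.residual.loc[tumor_ids],
            degenerate=fractions.degenerate.loc[tumor_ids],
        )
        pur = purity.loc[tumor_ids] if purity is not None and purity.loc[tumor_ids].notna().all() else None
        tab = correlate_with_gene(tumor_frac, gexpr, purity=pur)
        tab.insert(0, "gene", gid)
        corr_frames.append(tab)
    correlations = pd.concat(corr_frames)

    score_pvalues = pathway_summary["p_value"].to_dict()
    features = assemble_features(
        scores, score_pvalues, fractions, expr,
        p.hgf_id, p.met_id, top_k_pathways=p.top_k_pathways,
    )
    roc = train_classifier_cv(features, k_folds=p.k_folds,
                              seed=_child_seed(p.seed, 200))
    logger.info("classifier: AUC=%.3f accuracy=%.3f", roc.auc, roc.accuracy)

    survival_logrank = km = None
    if survival is not None:
        surv_feats = {}
        log2v = expr.log2_values()
        surv_feats["HGF"] = log2v.loc[p.hgf_id, tumor_ids]
        surv_feats["MET"] = log2v.loc[p.met_id, tumor_ids]
        for ct in fractions.fractions.columns:
            surv_feats[f"frac_{ct}"] = fractions.fractions.loc[tumor_ids, ct]
        surv_features = pd.DataFrame(surv_feats)
        survival_logrank = feature_logrank_table(surv_features, survival)
        if "group" in survival.columns:
            km = km_curves(survival)
        logger.info("survival: %d features tested", len(survival_logrank))

    return PipelineResult(
        activation=labels, degs=degs, enrichment=enr, pathways=pathways,
        scores=scores, pathway_summary=pathway_summary, fractions=fractions,
        correlations=correlations, features=features, roc=roc,
        survival_logrank=survival_logrank, km=km,
    )


def write_results(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame, **kw):
        paths[name] = outdir / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", **kw)

    _write("activation", result.activation.table, index_label="sample_id")
    _write("degs", result.degs)
    _write("enrichment", result.enrichment)
    A = pd.DataFrame({r.name: r.A for r in result.scores}).T
    DS = pd.DataFrame({r.name: r.DS for r in result.scores}).T
    _write("pathway_A", A, index_label="pathway")
    _write("pathway_DS", DS, index_label="pathway")
    _write("pathway_summary", result.pathway_summary)
    frac = result.fractions.fractions.copy()
    frac["abundance"] = result.fractions.abundance
    frac["residual"] = result.fractions.residual
    _write("fractions", frac, index_label="sample_id")
    _write("correlations", result.correlations)
    _write("features", result.features.X, index_label="sample_id")
    _write("predictions", result.roc.predictions, index_label="sample_id")
    _write("roc", result.roc.curve(), index=False)
    metrics = {
        "auc": result.roc.auc,
        "accuracy": result.roc.accuracy,
        "n_activated": int(len(result.activation.activated_samples)),
        "n_inactivated": int(len(result.activation.inactivated_samples)),
        "activated_pearson_r": result.activation.pearson_r,
        "activated_pearson_p": result.activation.pearson_p,
        "n_degs": int(len(result.degs)),
        "n_pathways_scored": len(result.scores),
    }
    paths["metrics"] = outdir / "metrics.json"
    paths["metrics"].write_text(json.dumps(metrics, indent=1, sort_keys=True))
    if result.survival_logrank is not None:
        _write("survival_logrank", result.survival_logrank)
    if result.km is not None:
        _write("km_curves", result.km, index=False)
    return paths


def run_pipeline(config_path: str | Path, outdir: str | Path | None = None) -> dict[str, Path]:
    """Run the full pipeline from a YAML config naming the input files.

    Expected keys: expression, metadata, immune_genes, gene_sets, signature,
    optional survival, optional output_dir, plus any
    :class:`PipelineParams` field (e.g. seed, n_perm, hgf_id).
    """
    config_path = Path(config_path)
    with open(config_path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent

    def _path(key):
        return (base / cfg[key]).resolve() if not Path(cfg[key]).is_absolute() else Path(cfg[key])

    meta = hio.read_metadata_tsv(_path("metadata"))
    expr = hio.read_expression_tsv(_path("expression"), sample_meta=meta)
    immune = hio.read_gene_list(_path("immune_genes"))
    if not any(g in expr.gene_ids for g in immune):
        raise InputError("immune gene list does not intersect the expression matrix")
    sets = hio.read_gmt(_path("gene_sets"))
    signature = hio.read_signature_tsv(_path("signature"))
    survival = hio.read_survival_tsv(_path("survival")) if "survival" in cfg else None

    params = PipelineParams(
        **{k: v for k, v in cfg.items() if k in PipelineParams.__dataclass_fields__}
    )
    result = analyze(expr, immune, sets, signature, survival, params)
    out = Path(outdir) if outdir is not None else base / cfg.get("output_dir", "results")
    return write_results(result, out)
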