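"""Weighted pathway imbalance scoring with a permutation-null degree score.

For a pathway P with m up-regulated and n down-regulated member genes, the
per-sample imbalance score is

    A(P) = log2( sqrt(sum_i w_i (X_i - mu_i)^2) /
                 sqrt(sum_j w_j (X_j - mu_j)^2) )

where i runs over up members, j over down members, X is the sample's
log2(x+1) expression, mu the gene's mean over a reference group (default:
inactivated tumors, standing in for the pathway-quiet state) and w a
co-expression network weight. A(P) = 0 means the weighted up- and
down-deviations balance; positive A means the up side dominates.

A(P) is standardized into the degree score DS(P) = (A - mu') / sd' where
mu' and sd' are the per-sample mean and standard deviation of A over
``n_perm`` (default 1000) random same-shape gene sets drawn without
replacement from a gene pool; each draw recomputes weights and reference
means for the drawn genes so the null mimics the full scoring procedure.

Weights (their computation is a design choice of this package): w_g is the
mean absolute Pearson correlation of gene g with the other member genes,
normalized to mean 1 over the pathway and floored at 1e-6 (a constant gene
contributes zero correlations and receives the floor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activation import ActivationLabels
from .diffexpr import welch_test, UP, DOWN
from .errors import InputError

logger = logging.getLogger(__name__)

WEIGHT_FLOOR = 1e-6


@dataclass
class PathwayDefinition:
    """A named pathway split into up- and down-regulated members."""

    name: str
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    weights: pd.Series | None = None  # one positive weight per member gene

    def __post_init__(self) -> None:
        self.up_genes = tuple(dict.fromkeys(self.up_genes))
        self.down_genes = tuple(dict.fromkeys(self.down_genes))
        if set(self.up_genes) & set(self.down_genes):
            raise InputError(f"pathway '{self.name}': up/down members overlap")
        if len(self.up_genes) < 1 or len(self.down_genes) < 1:
            raise InputError(
                f"pathway '{self.name}' is unscoreable: needs >= 1 up and >= 1 down gene"
            )
        if self.weights is not None and (self.weights <= 0).any():
            raise InputError(f"pathway '{self.name}': weights must be positive")

    @property
    def members(self) -> tuple[str, ...]:
        return self.up_genes + self.down_genes

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.up_genes), len(self.down_genes)


@dataclass
class NullSummary:
    """Per-sample permutation-null mean and SD of the imbalance score."""

    mu_prime: pd.Series
    sd_prime: pd.Series
    n_perm: int
    seed: int


@dataclass
class PathwayScoreResult:
    """Per-sample A and DS for one pathway plus its null summary."""

    name: str
    A: pd.Series
    DS: pd.Series
    null: NullSummary
    weights: pd.Series


def _abs_corr(X: np.ndarray) -> np.ndarray:
    """|Pearson| matrix over rows; constant rows correlate 0 with everything."""
    if X.shape[1] < 3:
        raise InputError("co-expression weights need >= 3 samples")
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant gene(s) receive zero correlations", constant.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.abs(np.corrcoef(X))
    C = np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(C, 1.0)
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    return C


def _weights_from_corr(C_sub: np.ndarray) -> np.ndarray:
    """Mean |r| with co-members, floored and normalized to mean 1."""
    k = C_sub.shape[-1]
    if k < 2:
        raise InputError("co-expression weights need >= 2 genes")
    raw = (C_sub.sum(axis=-1) - np.diagonal(C_sub, axis1=-2, axis2=-1)) / (k - 1)
    raw = np.maximum(raw, WEIGHT_FLOOR)
    return raw / raw.mean(axis=-1, keepdims=True)


def coexpression_weights(log2_expr: pd.DataFrame, genes) -> pd.Series:
    """Co-expression weights for ``genes`` over the samples of ``log2_expr``."""
    genes = list(dict.fromkeys(genes))
    missing = [g for g in genes if g not in log2_expr.index]
    if missing:
        raise InputError(f"genes absent from matrix: {missing[:5]}")
    C = _abs_corr(log2_expr.loc[genes].to_numpy(dtype=float))
    return pd.Series(_weights_from_corr(C), index=genes, name="weight")


def reference_means(log2_expr: pd.DataFrame, reference_samples) -> pd.Series:
    """Per-gene mean over the reference sample group."""
    ref = pd.Index(reference_samples)
    if len(ref) == 0:
        raise InputError("empty reference group")
    return log2_expr[ref].mean(axis=1)


def imbalance_scores(
    log2_expr: pd.DataFrame,
    pathway: PathwayDefinition,
    mu: pd.Series,
    weights: pd.Series | None = None,
) -> pd.Series:
    """A(P) for every sample column of ``log2_expr`` (NaN where undefined)."""
    w = weights if weights is not None else pathway.weights
    if w is None:
        raise InputError(f"pathway '{pathway.name}' has no weights")
    members = list(pathway.members)
    for g in members:
        if g not in log2_expr.index:
            raise InputError(f"pathway gene absent from matrix: {g}")
        if g not in mu.index:
            raise InputError(f"pathway gene absent from reference means: {g}")
    X = log2_expr.loc[members].to_numpy(dtype=float)
    dev2 = (X - mu.loc[members].to_numpy()[:, None]) ** 2
    wv = w.loc[members].to_numpy(dtype=float)
    m = len(pathway.up_genes)
    num = wv[:m] @ dev2[:m]
    den = wv[m:] @ dev2[m:]
    with np.errstate(divide="ignore", invalid="ignore"):
        A = 0.5 * (np.log2(num) - np.log2(den))
    A[(num == 0) | (den == 0)] = np.nan
    return pd.Series(A, index=log2_expr.columns, name=pathway.name)


def imbalance_A(sample_expr: pd.Series, pathway: PathwayDefinition, mu: pd.Series) -> float:
    """A(P) for a single sample (one expression value per gene)."""
    frame = sample_expr.to_frame(name="sample")
    return float(imbalance_scores(frame.loc[:, :], pathway, mu).iloc[0])


def permutation_null(
    log2_expr: pd.DataFrame,
    pathway_shape: tuple[int, int],
    gene_pool,
    reference_samples,
    n_perm: int = 1000,
    seed: int = 0,
) -> NullSummary:
    """Null mu'/sd' per sample over random same-shape gene sets.

    Each of the ``n_perm`` draws samples m + n genes without replacement
    from ``gene_pool`` (first m act as the up set), recomputes weights and
    reference means for the drawn genes, and scores every sample. The draw
    sequence is fully determined by ``seed``.
    """
    m, n = pathway_shape
    if m < 1 or n < 1:
        raise InputError("pathway shape needs m >= 1 and n >= 1")
    if n_perm < 2:
        raise InputError("n_perm must be >= 2")
    pool = list(dict.fromkeys(gene_pool))
    missing = [g for g in pool if g not in log2_expr.index]
    if missing:
        raise InputError(f"pool genes absent from matrix: {missing[:5]}")
    k = m + n
    if len(pool) < k:
        raise InputError(
            f"gene pool ({len(pool)}) smaller than pathway size ({k})"
        )

    X = log2_expr.loc[pool].to_numpy(dtype=float)
    mu = X[:, log2_expr.columns.get_indexer(pd.Index(reference_samples))].mean(axis=1)
    D = (X - mu[:, None]) ** 2
    C = _abs_corr(X)

    rng = np.random.default_rng(seed)
    # uniformly ordered sampling without replacement, vectorized over draws
    order = np.argsort(rng.random((n_perm, len(pool))), axis=1, kind="stable")
    draws = order[:, :k]

    n_samples = X.shape[1]
    mean_acc = np.zeros(n_samples)
    m2_acc = np.zeros(n_samples)
    count = np.zeros(n_samples)
    chunk = max(1, int(2e7 // (k * n_samples + 1)))
    for start in range(0, n_perm, chunk):
        d = draws[start:start + chunk]
        sub = C[d[:, :, None], d[:, None, :]]
        w = _weights_from_corr(sub)
        up, dn = d[:, :m], d[:, m:]
        num = np.einsum("di,dis->ds", w[:, :m], D[up])
        den = np.einsum("dj,djs->ds", w[:, m:], D[dn])
        with np.errstate(divide="ignore", invalid="ignore"):
            A = 0.5 * (np.log2(num) - np.log2(den))
        A[(num == 0) | (den == 0)] = np.nan
        ok = np.isfinite(A)
        mean_acc += np.where(ok, A, 0.0).sum(axis=0)
        m2_acc += np.where(ok, A * A, 0.0).sum(axis=0)
        count += ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_p = mean_acc / count
        var = (m2_acc - count * mu_p**2) / (count - 1)
    sd_p = np.sqrt(np.maximum(var, 0.0))
    return NullSummary(
        mu_prime=pd.Series(mu_p, index=log2_expr.columns, name="mu_prime"),
        sd_prime=pd.Series(sd_p, index=log2_expr.columns, name="sd_prime"),
        n_perm=n_perm,
        seed=seed,
    )


def deviation_DS(A: pd.Series, null: NullSummary) -> pd.Series:
    """DS = (A - mu') / sd'; undefined (NaN) where sd' = 0."""
    if not A.index.equals(null.mu_prime.index):
        raise InputError("sample mismatch between scores and null summary")
    sd = null.sd_prime.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ds = (A.to_numpy() - null.mu_prime.to_numpy()) / sd
    ds = np.where(sd == 0, np.nan, ds)
    return pd.Series(ds, index=A.index, name=A.name)


def score_pathway(
    log2_expr: pd.DataFrame,
    pathway: PathwayDefinition,
    gene_pool,
    reference_samples,
    n_perm: int = 1000,
    seed: int = 0,
) -> PathwayScoreResult:
    """Full scoring of one pathway: weights, A, permutation null, DS."""
    weights = (
        pathway.weights
        if pathway.weights is not None
        else coexpression_weights(log2_expr, pathway.members)
    )
    mu = reference_means(log2_expr, reference_samples)
    A = imbalance_scores(log2_expr, pathway, mu, weights)
    null = permutation_null(
        log2_expr, pathway.shape, gene_pool, reference_samples, n_perm, seed
    )
    return PathwayScoreResult(
        name=pathway.name, A=A, DS=deviation_DS(A, null), null=null, weights=weights
    )


def group_compare(ds: pd.Series, labels: ActivationLabels) -> tuple[float, float, str]:
    """Two-sided Welch comparison of DS between activation groups.

    Returns (t, p, direction) with direction 'up' when the activated group
    mean is higher.
    """
    act = ds.loc[ds.index.intersection(labels.activated_samples)].dropna()
    ina = ds.loc[ds.index.intersection(labels.inactivated_samples)].dropna()
    if len(act) < 2 or len(ina) < 2:
        raise InputError("group comparison needs >= 2 samples per group")
    t, _, p = welch_test(act.to_numpy(), ina.to_numpy())
    return t, p, UP if act.mean() > ina.mean() else DOWN
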