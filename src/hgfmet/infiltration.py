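"""Signature-based immune-cell deconvolution and correlation with genes.

Per-sample cell-type fractions are estimated by non-negative least squares
of the sample's linear-scale marker-gene expression against a signature
matrix, then normalized onto the simplex. The unnormalized coefficient sum
is kept as a per-sample *abundance* (an absolute-infiltration proxy: with a
common signature, a sample with twice the immune content has twice the
coefficient sum). Fractions are then correlated with a gene's expression
(Pearson; optionally a first-order partial correlation controlling for
tumor purity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .containers import ExpressionMatrix, SignatureMatrix
from .errors import InputError


@dataclass
class InfiltrationFractions:
    """Samples x cell-type simplex fractions with reconstruction diagnostics.

    ``fractions`` rows sum to 1; ``abundance`` is the raw NNLS coefficient
    sum (absolute-infiltration proxy); ``residual`` is the relative
    reconstruction error ||b - S f|| / ||b||; ``degenerate`` flags samples
    where NNLS returned the all-zero solution and uniform fractions were
    substituted.
    """

    fractions: pd.DataFrame
    abundance: pd.Series
    residual: pd.Series
    degenerate: pd.Series

    def __post_init__(self) -> None:
        arr = self.fractions.to_numpy()
        if (arr < 0).any():
            raise InputError("fractions must be non-negative")
        if not np.allclose(arr.sum(axis=1), 1.0):
            raise InputError("fraction rows must sum to 1")


def deconvolve_sample(sample_expr: pd.Series, signature: SignatureMatrix):
    """NNLS deconvolution of one sample; returns (fractions, abundance,
    residual, degenerate_flag)."""
    S = signature.values
    common = S.index.intersection(sample_expr.index)
    if len(common) < len(S.index) * 0.5:
        missing = sorted(S.index.difference(sample_expr.index))
        raise InputError(
            f"marker overlap below 50%: missing {len(missing)} markers "
            f"(e.g. {missing[:5]})"
        )
    if len(common) < S.shape[1]:
        raise InputError("need at least as many shared markers as cell types")
    A = S.loc[common].to_numpy(dtype=float)
    b = sample_expr.loc[common].to_numpy(dtype=float)
    coef, _ = nnls(A, b)
    total = coef.sum()
    norm_b = np.linalg.norm(b)
    resid = np.linalg.norm(b - A @ coef) / norm_b if norm_b > 0 else 0.0
    if total == 0:
        frac = np.full(S.shape[1], 1.0 / S.shape[1])
        return pd.Series(frac, index=S.columns), 0.0, float(resid), True
    return pd.Series(coef / total, index=S.columns), float(total), float(resid), False


def deconvolve(expr: ExpressionMatrix, signature: SignatureMatrix) -> InfiltrationFractions:
    """Deconvolve every sample of the cohort (linear-scale expression)."""
    rows, abund, resid, degen = [], [], [], []
    marker_expr = expr.values.loc[expr.gene_ids.intersection(signature.marker_genes)]
    for sid in expr.sample_ids:
        f, a, r, d = deconvolve_sample(marker_expr[sid], signature)
        rows.append(f)
        abund.append(a)
        resid.append(r)
        degen.append(d)
    idx = expr.sample_ids
    return InfiltrationFractions(
        fractions=pd.DataFrame(rows, index=idx),
        abundance=pd.Series(abund, index=idx, name="abundance"),
        residual=pd.Series(resid, index=idx, name="residual"),
        degenerate=pd.Series(degen, index=idx, name="degenerate"),
    )


def _partial_pearson(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    """First-order partial correlation of x and y controlling for z."""
    zc = np.column_stack([np.ones_like(z), z])
    rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
    ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    df = n - 3
    if df <= 0 or abs(r) >= 1.0:
        return r, float("nan")
    t = r * np.sqrt(df / (1 - r**2))
    return r, float(2 * stats.t.sf(abs(t), df))


def correlate_with_gene(
    fractions: InfiltrationFractions,
    gene_expr: pd.Series,
    purity: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson r and p of each cell-type fraction with a gene's expression.

    With ``purity`` supplied, partial correlations controlling for purity
    are added (``partial_r``, ``partial_p``). Constant fraction columns are
    reported as undefined (NaN), not as zero correlation.
    """
    common = fractions.fractions.index.intersection(gene_expr.index)
    if len(common) < 4:
        raise InputError("correlation needs at least 4 samples")
    g = gene_expr.loc[common].to_numpy(dtype=float)
    if purity is not None:
        pur = purity.loc[common]
        if pur.isna().any():
            raise InputError("purity contains missing values on the correlated samples")
        if ((pur < 0) | (pur > 1)).any():
            raise InputError("purity must lie in [0, 1]")
    rows = []
    for ct in fractions.fractions.columns:
        f = fractions.fractions.loc[common, ct].to_numpy(dtype=float)
        if f.std() == 0 or g.std() == 0:
            row = {"cell_type": ct, "r": np.nan, "p": np.nan}
        else:
            r, p = stats.pearsonr(f, g)
            row = {"cell_type": ct, "r": float(r), "p": float(p)}
        if purity is not None:
            pr, pp = (
                _partial_pearson(f, g, pur.to_numpy(dtype=float))
                if np.std(f) > 0 and np.std(g) > 0
                else (np.nan, np.nan)
            )
            row["partial_r"], row["partial_p"] = pr, pp
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell_type")
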