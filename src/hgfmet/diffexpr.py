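"""Welch two-sample screening of immune genes between activation groups.

Genes are tested on the log2(x + 1) scale with an unequal-variance t
statistic and Welch-Satterthwaite degrees of freedom; genes with a
two-sided p below ``alpha`` (default 0.05, no multiplicity correction by
default — fold change is reported but never used as a filter) form the
differential table. Benjamini-Hochberg adjustment is available as an
opt-in flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .activation import ActivationLabels, ACTIVATED, INACTIVATED
from .enrichment import bh_adjust
from .errors import InputError

UP = "up"
DOWN = "down"


def welch_test(group_a, group_b) -> tuple[float, float, float]:
    """Two-sided Welch test; returns (t, df, p).

    Degenerate conventions: if both groups have zero variance the test is
    undefined — p = 1 when the means agree, p = 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise InputError("welch_test expects 1-D samples")
    if a.size < 2 or b.size < 2:
        raise InputError("welch_test needs at least 2 values per group")
    t, df, p = _welch_arrays(a[:, None], b[:, None])
    return float(t[0]), float(df[0]), float(p[0])


def _welch_arrays(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch test over columns of ``a`` (n_a x m) and ``b`` (n_b x m)."""
    na, nb = a.shape[0], b.shape[0]
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    var_a = a.var(axis=0, ddof=1)
    var_b = b.var(axis=0, ddof=1)
    se2 = var_a / na + var_b / nb
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1)
        )
    degenerate = se2 == 0
    t = np.where(degenerate, 0.0, t)
    df = np.where(degenerate, float(na + nb - 2), df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # both variances zero: p decided purely by whether the means agree
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return t, df, np.clip(p, 0.0, 1.0)


def screen_degs(
    expr: ExpressionMatrix,
    labels: ActivationLabels,
    immune_genes,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    adjust: str = "none",
) -> pd.DataFrame:
    """Welch-screen immune genes between activated and inactivated tumors.

    Returns only genes passing the threshold (raw p < alpha, or BH q < alpha
    when ``adjust='bh'``), sorted by p then gene id. Columns: mean_activated,
    mean_inactivated (log2 scale), log2_fc, t_statistic, df, p_value,
    q_value, direction.
    """
    genes = [g for g in dict.fromkeys(immune_genes) if g in expr.gene_ids]
    if not genes:
        raise InputError("immune gene list does not intersect the expression matrix")
    if adjust not in ("none", "bh"):
        raise InputError(f"unknown adjustment '{adjust}' (use 'none' or 'bh')")
    act = labels.activated_samples
    ina = labels.inactivated_samples
    if len(act) < 2 or len(ina) < 2:
        raise InputError("screen_degs needs >= 2 samples per activation group")

    log2x = np.log2(expr.values.loc[genes].astype(float) + pseudocount)
    a = log2x[act].to_numpy().T  # samples x genes
    b = log2x[ina].to_numpy().T
    t, df, p = _welch_arrays(a, b)
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    lin_a = expr.values.loc[genes, act].mean(axis=1).to_numpy()
    lin_b = expr.values.loc[genes, ina].mean(axis=1).to_numpy()
    log2_fc = np.log2((lin_a + pseudocount) / (lin_b + pseudocount))
    q = bh_adjust(p)

    table = pd.DataFrame(
        {
            "mean_activated": mean_a,
            "mean_inactivated": mean_b,
            "log2_fc": log2_fc,
            "t_statistic": t,
            "df": df,
            "p_value": p,
            "q_value": q,
            "direction": np.where(mean_a > mean_b, UP, DOWN),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    crit = table["q_value"] if adjust == "bh" else table["p_value"]
    table = table[crit < alpha]
    return table.sort_values(["p_value", "gene_id"], kind="mergesort")


def split_by_direction(deg_table: pd.DataFrame) -> tuple[frozenset[str], frozenset[str]]:
    """Gene ids of the up- and down-regulated rows of a DEG table."""
    up = frozenset(deg_table.index[deg_table["direction"] == UP])
    down = frozenset(deg_table.index[deg_table["direction"] == DOWN])
    return up, down
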