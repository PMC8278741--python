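"""Label tumor samples as HGF/c-MET pathway activated or inactivated.

In pathway-activated samples the ligand (HGF) and its receptor (MET) are
expected to be co-expressed, so after each gene is min-max scaled to [0, 1]
over the tumor samples their ratio sits near 1. Samples whose scaled
HGF/MET ratio falls inside an inclusive window (default [0.5, 1.5]) are
labelled *activated*, all others *inactivated*. A sample whose scaled MET is
exactly 0 has an undefined ratio and is labelled inactivated (an
unexpressed receptor cannot support ligand signalling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CANCER_COL, ExpressionMatrix
from .errors import DegenerateInputError, InputError

ACTIVATED = "activated"
INACTIVATED = "inactivated"


@dataclass
class ActivationLabels:
    """Per-tumor-sample activation call with the scaled values behind it.

    ``table`` columns: scaled_hgf, scaled_met, ratio (NaN when undefined),
    label. ``pearson_r``/``pearson_p`` describe HGF-MET correlation on raw
    expression within the activated group (NaN when that group has < 3
    samples).
    """

    table: pd.DataFrame
    pearson_r: float
    pearson_p: float

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    @property
    def activated_samples(self) -> pd.Index:
        return self.table.index[self.table["label"] == ACTIVATED]

    @property
    def inactivated_samples(self) -> pd.Index:
        return self.table.index[self.table["label"] == INACTIVATED]


def scale_minmax(values) -> np.ndarray:
    """Scale a vector to [0, 1] by (x - min) / (max - min)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InputError("min-max scaling needs at least 2 values")
    if not np.isfinite(arr).all():
        raise InputError("min-max scaling requires finite values")
    if (arr < 0).any():
        raise InputError("expression values must be non-negative")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise DegenerateInputError("constant vector cannot be min-max scaled")
    return (arr - lo) / (hi - lo)


def classify_activation(
    expr: ExpressionMatrix,
    hgf_id: str = "HGF",
    met_id: str = "MET",
    lo: float = 0.5,
    hi: float = 1.5,
    per_cancer_scaling: bool = False,
) -> ActivationLabels:
    """Call activation for every tumor sample from the scaled HGF/MET ratio.

    Scaling is computed over tumor samples only (normals carry no label);
    with ``per_cancer_scaling`` the min-max runs within each cancer type.
    """
    for gid in (hgf_id, met_id):
        if gid not in expr.gene_ids:
            raise InputError(f"gene not found: {gid}")
    tumor_ids = expr.tumor_samples
    if len(tumor_ids) < 3:
        raise InputError("activation labelling needs at least 3 tumor samples")

    hgf_raw = expr.values.loc[hgf_id, tumor_ids].to_numpy(dtype=float)
    met_raw = expr.values.loc[met_id, tumor_ids].to_numpy(dtype=float)

    if per_cancer_scaling:
        cancer = expr.sample_meta.loc[tumor_ids, CANCER_COL]
        scaled_h = np.empty_like(hgf_raw)
        scaled_m = np.empty_like(met_raw)
        for ct in cancer.unique():
            mask = (cancer == ct).to_numpy()
            scaled_h[mask] = scale_minmax(hgf_raw[mask])
            scaled_m[mask] = scale_minmax(met_raw[mask])
    else:
        scaled_h = scale_minmax(hgf_raw)
        scaled_m = scale_minmax(met_raw)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(scaled_m > 0, scaled_h / scaled_m, np.nan)
    in_window = (ratio >= lo) & (ratio <= hi) & np.isfinite(ratio)
    label = np.where(in_window, ACTIVATED, INACTIVATED)

    table = pd.DataFrame(
        {
            "scaled_hgf": scaled_h,
            "scaled_met": scaled_m,
            "ratio": ratio,
            "label": label,
        },
        index=tumor_ids,
    )
    act = table.index[table["label"] == ACTIVATED]
    if len(act) >= 3:
        r, p = stats.pearsonr(
            expr.values.loc[hgf_id, act].to_numpy(dtype=float),
            expr.values.loc[met_id, act].to_numpy(dtype=float),
        )
    else:
        r, p = float("nan"), float("nan")
    return ActivationLabels(table=table, pearson_r=float(r), pearson_p=float(p))
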