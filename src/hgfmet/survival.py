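"""Log-rank survival comparison between median-dichotomized feature groups.

Each continuous feature (HGF, MET, each cell fraction, ...) splits the
cohort at its median (ties at the median go to the low group); the two-group
log-rank statistic is the squared sum of observed-minus-expected events in
one group over the hypergeometric variance accumulated at each distinct
event time, referred to a chi-square with 1 df. Kaplan-Meier curves are
emitted for plotting via lifelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .errors import DegenerateInputError, InputError

LOW = "low"
HIGH = "high"


def median_split(values: pd.Series) -> pd.Series:
    """Split samples at the median: high iff value > median, ties to low."""
    v = values.dropna()
    if len(v) < 4:
        raise InputError("median split needs at least 4 samples")
    med = float(v.median())
    if v.nunique() == 1:
        raise DegenerateInputError("all values identical: degenerate median split")
    labels = np.where(v.to_numpy(dtype=float) > med, HIGH, LOW)
    if (labels == HIGH).sum() == 0:
        raise DegenerateInputError("median split produced an empty high group")
    return pd.Series(labels, index=v.index, name="group")


def logrank(surv: pd.DataFrame, group_col: str = "group") -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p).

    ``surv`` needs columns time, event and a two-level group column, with
    at least one observed event per group.
    """
    required = {"time", "event", group_col}
    if not required <= set(surv.columns):
        raise InputError(f"survival table needs columns {sorted(required)}")
    groups = pd.unique(surv[group_col])
    if len(groups) != 2:
        raise InputError(f"log-rank needs exactly 2 groups, got {len(groups)}")
    if (surv["time"] <= 0).any():
        raise InputError("survival times must be > 0")
    events_per_group = surv.groupby(group_col)["event"].sum()
    if (events_per_group < 1).any():
        raise InputError("each group needs at least one observed event")

    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    in_g1 = (surv[group_col] == groups[0]).to_numpy()

    order = np.argsort(time, kind="stable")
    time, event, in_g1 = time[order], event[order], in_g1[order]

    o_minus_e = 0.0
    var = 0.0
    n = len(time)
    i = 0
    at_risk_total = n
    at_risk_g1 = int(in_g1.sum())
    while i < n:
        t = time[i]
        j = i
        d = d1 = removed = removed_g1 = 0
        while j < n and time[j] == t:
            d += event[j]
            d1 += event[j] * in_g1[j]
            removed += 1
            removed_g1 += int(in_g1[j])
            j += 1
        if d > 0 and at_risk_total > 1:
            frac = at_risk_g1 / at_risk_total
            o_minus_e += d1 - d * frac
            var += (
                d
                * frac
                * (1 - frac)
                * (at_risk_total - d)
                / (at_risk_total - 1)
            )
        at_risk_total -= removed
        at_risk_g1 -= removed_g1
        i = j
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def km_curves(surv: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Kaplan-Meier survival coordinates per group (long format)."""
    frames = []
    for g, sub in surv.groupby(group_col):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        sf = kmf.survival_function_
        frames.append(
            pd.DataFrame(
                {"group": str(g), "time": sf.index.to_numpy(),
                 "survival": sf.iloc[:, 0].to_numpy()}
            )
        )
    return pd.concat(frames, ignore_index=True)


def feature_logrank_table(
    features: pd.DataFrame, surv: pd.DataFrame
) -> pd.DataFrame:
    """Median-split every feature column and log-rank test it.

    Returns one row per feature: chi2, p, n_low, n_high (NaN-filled for
    features with a degenerate split or group without events).
    """
    common = features.index.intersection(surv.index)
    if len(common) < 4:
        raise InputError("too few samples shared between features and survival")
    rows = []
    for feat in features.columns:
        try:
            groups = median_split(features.loc[common, feat])
            tab = surv.loc[groups.index, ["time", "event"]].copy()
            tab["group"] = groups
            chi2, p = logrank(tab)
            rows.append((feat, chi2, p, int((groups == LOW).sum()),
                         int((groups == HIGH).sum())))
        except (DegenerateInputError, InputError):
            rows.append((feat, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["feature", "chi2", "p_value", "n_low", "n_high"]
    ).set_index("feature")
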