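"""Tumor-vs-normal diagnostic classifier over integrated immune features.

Features per sample: the estimated immune cell fractions, the degree
scores of the top-k pathways (ranked by the activated-vs-inactivated
comparison p-value) and log2 HGF / log2 MET. A single-hidden-layer
feed-forward network (16 logistic units, weighted cross-entropy, full-batch
gradient descent with momentum, seed-controlled initialization) is
evaluated by stratified k-fold cross-validation; out-of-fold probabilities
are pooled into one ROC. Standardization parameters are fit on training
folds only. Class imbalance is handled with inverse-frequency sample
weights (normal tissue is the minority class in the cohorts this targets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve as sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .containers import CANCER_COL, TUMOR_COL, ExpressionMatrix
from .infiltration import InfiltrationFractions
from .pathway import PathwayScoreResult
from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Samples x features with a binary tumor/normal label."""

    X: pd.DataFrame
    y: pd.Series          # 1 = tumor, 0 = normal
    cancer_type: pd.Series

    def __post_init__(self) -> None:
        if self.X.isna().to_numpy().any():
            raise InputError("feature table contains missing values")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise InputError("labels must be binary 0/1")


@dataclass
class ROCResult:
    """Pooled cross-validated ROC with AUC and 0.5-threshold accuracy."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    accuracy: float
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def assemble_features(
    scores: list[PathwayScoreResult],
    score_pvalues: dict[str, float],
    fractions: InfiltrationFractions,
    expr: ExpressionMatrix,
    hgf_id: str = "HGF",
    met_id: str = "MET",
    top_k_pathways: int = 20,
    samples=None,
) -> FeatureTable:
    """Build the integrated feature table for the requested samples.

    Pathways are ranked by their group-comparison p-value; if fewer than
    ``top_k_pathways`` are available all are used with a warning. By
    default all samples of the cohort (tumors of the cancer under test plus
    every normal) are included.
    """
    ids = pd.Index(samples) if samples is not None else expr.sample_ids
    ranked = sorted(scores, key=lambda s: (score_pvalues.get(s.name, 1.0), s.name))
    if len(ranked) < top_k_pathways:
        logger.warning(
            "only %d scored pathways available (requested top %d): using all",
            len(ranked), top_k_pathways,
        )
    chosen = ranked[:top_k_pathways]

    blocks = {}
    frac = fractions.fractions
    missing = ids.difference(frac.index)
    if len(missing):
        raise InputError(f"samples missing from fractions: {list(missing)[:5]}")
    for ct in frac.columns:
        blocks[f"frac_{ct}"] = frac.loc[ids, ct]
    for s in chosen:
        missing = ids.difference(s.DS.index)
        if len(missing):
            raise InputError(
                f"samples missing from pathway scores ({s.name}): {list(missing)[:5]}"
            )
        blocks[f"ds_{s.name}"] = s.DS.loc[ids]
    log2v = expr.log2_values()
    for gid, col in ((hgf_id, "log2_HGF"), (met_id, "log2_MET")):
        if gid not in expr.gene_ids:
            raise InputError(f"gene not found: {gid}")
        blocks[col] = log2v.loc[gid, ids]
    X = pd.DataFrame(blocks, index=ids)
    # degree scores can be NaN for degenerate nulls; those columns are unusable
    X = X.dropna(axis=1)
    y = expr.sample_meta.loc[ids, TUMOR_COL].astype(int).rename("label")
    return FeatureTable(X=X, y=y, cancer_type=expr.sample_meta.loc[ids, CANCER_COL])


class NeuralNetClassifier:
    """Minimal 1-hidden-layer logistic network trained by gradient descent.

    Deterministic given ``seed``; supports per-sample weights (weighted
    cross-entropy). Inputs are expected standardized by the caller.
    """

    def __init__(
        self,
        hidden: int = 16,
        epochs: int = 2000,
        learning_rate: float = 0.3,
        momentum: float = 0.9,
        l2: float = 1e-4,
        seed: int = 0,
    ) -> None:
        self.hidden = hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.l2 = l2
        self.seed = seed

    @staticmethod
    def _sigmoid(z: np.ndarray) -> np.ndarray:
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out

    def fit(self, X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, d = X.shape
        if sample_weight is None:
            sample_weight = np.ones(n)
        w = sample_weight / sample_weight.sum()
        rng = np.random.default_rng(self.seed)
        self.W1 = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, self.hidden))
        self.b1 = np.zeros(self.hidden)
        self.W2 = rng.normal(0.0, 1.0 / np.sqrt(self.hidden), size=self.hidden)
        self.b2 = 0.0
        vW1 = np.zeros_like(self.W1)
        vb1 = np.zeros_like(self.b1)
        vW2 = np.zeros_like(self.W2)
        vb2 = 0.0
        for _ in range(self.epochs):
            h = self._sigmoid(X @ self.W1 + self.b1)
            p = self._sigmoid(h @ self.W2 + self.b2)
            delta = (p - y) * w  # d(weighted BCE)/d(logit)
            gW2 = h.T @ delta + self.l2 * self.W2
            gb2 = delta.sum()
            dh = np.outer(delta, self.W2) * h * (1 - h)
            gW1 = X.T @ dh + self.l2 * self.W1
            gb1 = dh.sum(axis=0)
            vW2 = self.momentum * vW2 - self.learning_rate * gW2
            vb2 = self.momentum * vb2 - self.learning_rate * gb2
            vW1 = self.momentum * vW1 - self.learning_rate * gW1
            vb1 = self.momentum * vb1 - self.learning_rate * gb1
            self.W2 += vW2
            self.b2 += vb2
            self.W1 += vW1
            self.b1 += vb1
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        h = self._sigmoid(np.asarray(X, dtype=float) @ self.W1 + self.b1)
        return self._sigmoid(h @ self.W2 + self.b2)


def roc_auc(scores, labels) -> ROCResult:
    """ROC by threshold sweep; AUC by trapezoid (equals normalized
    Mann-Whitney U)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not np.isfinite(s).all():
        raise InputError("scores must be finite")
    if len(np.unique(y)) != 2:
        raise InputError("both classes must be present")
    fpr, tpr, thr = sk_roc_curve(y, s)
    area = float(sk_auc(fpr, tpr))
    accuracy = float(((s > 0.5).astype(int) == y).mean())
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=area, accuracy=accuracy)


def train_classifier_cv(
    features: FeatureTable,
    k_folds: int = 5,
    seed: int = 0,
    **nn_kwargs,
) -> ROCResult:
    """Stratified k-fold CV of the network; pooled out-of-fold ROC.

    Standardization (mean/SD) and inverse-frequency class weights are
    computed on each training fold only.
    """
    X = features.X.to_numpy(dtype=float)
    y = features.y.to_numpy(dtype=int)
    counts = np.bincount(y, minlength=2)
    if (counts < k_folds).any():
        raise InputError(
            f"each class needs >= k_folds={k_folds} members (have {counts.tolist()}); "
            "use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    oof = np.empty(len(y))
    fold_of = np.empty(len(y), dtype=int)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr, Xte = (X[tr] - mu) / sd, (X[te] - mu) / sd
        freq = np.bincount(y[tr], minlength=2)
        sw = (len(tr) / (2.0 * freq))[y[tr]]
        net = NeuralNetClassifier(seed=seed + fold, **nn_kwargs)
        net.fit(Xtr, y[tr], sample_weight=sw)
        oof[te] = net.predict_proba(Xte)
        fold_of[te] = fold
    result = roc_auc(oof, y)
    result.predictions = pd.DataFrame(
        {"probability": oof, "label": y, "fold": fold_of}, index=features.X.index
    )
    return result
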