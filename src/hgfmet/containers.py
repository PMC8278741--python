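"""In-memory containers shared by all pipeline stages.

Expression data travel as a genes x samples :class:`pandas.DataFrame` wrapped
in :class:`ExpressionMatrix` together with per-sample metadata (tumor/normal
flag, cancer type, optional tumor purity). Gene sets are plain frozensets
keyed by name in :class:`GeneSetCollection`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

TUMOR_COL = "is_tumor"
CANCER_COL = "cancer_type"
PURITY_COL = "purity"


@dataclass
class ExpressionMatrix:
    """Non-negative expression values (genes in rows, samples in columns).

    Parameters
    ----------
    values
        genes x samples DataFrame; index are unique gene identifiers and
        columns unique sample identifiers. All entries must be finite and
        >= 0 (a normalized linear scale, e.g. level-3 style RSEM values).
    sample_meta
        One row per sample (same order as ``values.columns``) with at least
        ``is_tumor`` (bool) and ``cancer_type`` (str); ``purity`` in [0, 1]
        is optional and may be NaN.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise InputError(f"duplicate gene id: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise InputError(f"duplicate sample id: {dup}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise InputError("expression matrix contains missing or non-finite values")
        if (arr < 0).any():
            raise InputError("expression matrix contains negative values")
        if TUMOR_COL not in self.sample_meta.columns:
            raise InputError(f"sample metadata lacks required column '{TUMOR_COL}'")
        if not self.sample_meta.index.equals(self.values.columns):
            missing = self.values.columns.difference(self.sample_meta.index)
            if len(missing):
                raise InputError(f"samples missing from metadata: {list(missing)[:5]}")
            self.sample_meta = self.sample_meta.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def tumor_samples(self) -> pd.Index:
        mask = self.sample_meta[TUMOR_COL].astype(bool)
        return self.sample_ids[mask.to_numpy()]

    @property
    def normal_samples(self) -> pd.Index:
        mask = ~self.sample_meta[TUMOR_COL].astype(bool)
        return self.sample_ids[mask.to_numpy()]

    def log2_values(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """log2(x + pseudocount) view used by the testing and scoring stages."""
        return np.log2(self.values + pseudocount)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = pd.Index(sample_ids)
        return ExpressionMatrix(self.values[ids], self.sample_meta.loc[ids])


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics: name, description, members)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise InputError(f"gene set '{name}' is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class SignatureMatrix:
    """Marker-gene x cell-type reference expression for deconvolution."""

    values: pd.DataFrame  # marker genes x cell types, non-negative

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise InputError("signature matrix needs at least 2 cell types")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise InputError(f"duplicate marker gene in signature: {dup}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise InputError("signature matrix must be finite and non-negative")
        cols = self.values.T.to_numpy()
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if np.allclose(cols[i], cols[j]):
                    raise InputError(
                        "signature matrix has identical cell-type columns: "
                        f"{self.values.columns[i]} and {self.values.columns[j]}"
                    )

    @property
    def marker_genes(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns
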