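"""Readers and writers for the plain-text formats the pipeline consumes.

All tables are tab-separated UTF-8 with a ``.`` decimal point and no quoting.
Expression matrices are genes x samples with the gene identifier in the
first column; gene sets use the standard GMT layout
(``name<TAB>description<TAB>gene1<TAB>gene2...``).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CANCER_COL,
    PURITY_COL,
    TUMOR_COL,
    ExpressionMatrix,
    GeneSetCollection,
    SignatureMatrix,
)
from .errors import FormatError

logger = logging.getLogger(__name__)


def _read_numeric_table(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id: {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~np.isfinite(numeric)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{what} {path.name}: missing or non-numeric value at "
            f"gene '{numeric.index[r]}', sample '{numeric.columns[c]}'"
        )
    if (numeric.to_numpy() < 0).any():
        r, c = np.argwhere((numeric.to_numpy() < 0))[0]
        raise FormatError(
            f"{what} {path.name}: negative value at gene "
            f"'{numeric.index[r]}', sample '{numeric.columns[c]}'"
        )
    return numeric.astype(float)


def read_expression_tsv(path: str | Path, sample_meta: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    If ``sample_meta`` is omitted, every sample is flagged as tumor with an
    unknown cancer type (callers normally pair this with
    :func:`read_metadata_tsv`).
    """
    values = _read_numeric_table(path, "expression matrix")
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {TUMOR_COL: True, CANCER_COL: "unknown"}, index=values.columns
        )
    return ExpressionMatrix(values, sample_meta)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata: sample_id, is_tumor, cancer_type[, purity]."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if TUMOR_COL not in meta.columns:
        raise FormatError(f"metadata {Path(path).name}: missing column '{TUMOR_COL}'")
    meta[TUMOR_COL] = meta[TUMOR_COL].astype(int).astype(bool)
    if PURITY_COL in meta.columns:
        p = meta[PURITY_COL].dropna()
        if ((p < 0) | (p > 1)).any():
            raise FormatError(f"metadata {Path(path).name}: purity outside [0, 1]")
    return meta


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out[TUMOR_COL] = out[TUMOR_COL].astype(int)
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (>= 3 tab-separated fields per line)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT {Path(path).name}: line {lineno} has "
                    f"{len(fields)} fields (need name, description, >=1 gene)"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if len(set(genes)) < len(genes):
                logger.warning(
                    "GMT %s line %d (%s): duplicate genes de-duplicated",
                    Path(path).name, lineno, name,
                )
            if name in sets:
                raise FormatError(f"GMT {Path(path).name}: duplicate set name '{name}'")
            sets[name] = frozenset(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene per line; blank lines skipped, order preserved, de-duplicated."""
    seen: dict[str, None] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            g = line.strip()
            if g:
                seen.setdefault(g, None)
    return list(seen)


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_signature_tsv(path: str | Path) -> SignatureMatrix:
    return SignatureMatrix(_read_numeric_table(path, "signature matrix"))


def write_signature_tsv(sig: SignatureMatrix, path: str | Path) -> None:
    sig.values.to_csv(path, sep="\t", index_label="gene_id")


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    """Read sample_id, time, event[, group] survival records."""
    surv = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in surv.columns:
            raise FormatError(f"survival table {Path(path).name}: missing column '{col}'")
    if (surv["time"] <= 0).any():
        raise FormatError(f"survival table {Path(path).name}: non-positive time")
    if not surv["event"].isin([0, 1]).all():
        raise FormatError(f"survival table {Path(path).name}: event must be 0/1")
    return surv


def write_survival_tsv(surv: pd.DataFrame, path: str | Path) -> None:
    surv.to_csv(path, sep="\t", index_label="sample_id")
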