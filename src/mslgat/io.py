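"""Readers and writers for the tab-delimited inputs of the pipeline.

All tables are UTF-8, tab-delimited, with a header row.  Missing values
(``NA`` or empty cells) are rejected with an error naming the file — the
pipeline expects fully observed gene-level summaries, not raw probe/variant
data.

Dialects
--------
mutations    : ``Tumor_Sample_Barcode``, ``Hugo_Symbol``, ``Variant_Classification``
               (one record per row; a MAF-column subset)
matrix       : genes as rows, samples as columns, first column ``gene_id``
               (used for expression, methylation beta values and CNV calls)
differential : ``gene``, ``log2FC``, ``pvalue`` and optionally ``qvalue``
ppi          : ``gene_a``, ``gene_b`` and optionally ``confidence``
labels       : ``gene``, ``label`` with label in {0, 1}
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

MUTATION_COLUMNS = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]


class TableFormatError(ValueError):
    """Raised when an input table violates the expected dialect."""


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    if ((df == "NA") | (df == "")).to_numpy().any():
        raise TableFormatError(f"{path}: missing values ('NA' or empty cells) are not allowed")
    return df


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Somatic mutation records in the MAF-subset dialect."""
    return _read_tsv(path, MUTATION_COLUMNS)[MUTATION_COLUMNS]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Gene × sample numeric matrix; genes indexed by the ``gene_id`` column."""
    df = _read_tsv(path, ["gene_id"])
    df = df.set_index("gene_id")
    try:
        return df.astype(float)
    except ValueError as err:
        raise TableFormatError(f"{path}: non-numeric matrix entry ({err})") from None


def read_differential(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["gene", "log2FC", "pvalue"])
    out = pd.DataFrame({
        "gene": df["gene"],
        "log2FC": df["log2FC"].astype(float),
        "pvalue": df["pvalue"].astype(float),
    })
    if "qvalue" in df.columns:
        out["qvalue"] = df["qvalue"].astype(float)
    if out["gene"].duplicated().any():
        dup = out.loc[out["gene"].duplicated(), "gene"].iloc[0]
        raise TableFormatError(f"{path}: duplicate gene {dup!r} in differential table")
    if ((out["pvalue"] < 0) | (out["pvalue"] > 1)).any():
        raise TableFormatError(f"{path}: p-values outside [0, 1]")
    return out


def read_ppi(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["gene_a", "gene_b"])
    out = df[["gene_a", "gene_b"]].copy()
    out["confidence"] = df["confidence"].astype(float) if "confidence" in df.columns else 1.0
    return out


def read_labels(path: str | Path) -> pd.Series:
    df = _read_tsv(path, ["gene", "label"])
    labels = df["label"].astype(int)
    if not labels.isin([0, 1]).all():
        raise TableFormatError(f"{path}: labels must be 0 or 1")
    return pd.Series(labels.to_numpy(), index=df["gene"].to_numpy(), name="label")


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_predictions(genes, probabilities, labels, path: str | Path) -> None:
    pd.DataFrame({
        "gene": genes,
        "probability": np.asarray(probabilities, dtype=float),
        "label": np.asarray(labels, dtype=int),
    }).to_csv(path, sep="\t", index=False)
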