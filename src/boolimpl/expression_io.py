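"""Expression-matrix I/O and the dynamic-range gene filter.

Matrices are genes x samples on a log2 scale (log2(TPM+1) for RNA-seq
abundances), stored as a tab-delimited file whose first column is the gene
identifier and whose header row carries the sample identifiers.  Sample
class labels (e.g. 0 = control, 1 = case) come from a separate two-column
annotation table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .stepminer import TritMatrix

__all__ = [
    "ExpressionMatrix",
    "read_matrix",
    "write_matrix",
    "read_annotations",
    "log2_tpm_transform",
    "filter_dynamic_range",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale expression values.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns. All values
        must be finite; missing values are rejected.
    labels
        Optional Series mapping sample id -> class label. Every labelled
        sample must be a column of ``data``.
    """

    data: pd.DataFrame
    labels: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}; resolve duplicates first")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        vals = self.data.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value at gene {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        if self.labels is not None:
            unknown = self.labels.index.difference(self.data.columns)
            if len(unknown):
                raise ValueError(
                    f"annotation sample {unknown[0]!r} not present in matrix"
                )

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def label_vector(self) -> np.ndarray:
        """Labels aligned to sample order; raises if any sample is unlabelled."""
        if self.labels is None:
            raise ValueError("matrix has no sample labels attached")
        missing = self.data.columns.difference(self.labels.index)
        if len(missing):
            raise ValueError(f"sample {missing[0]!r} has no label")
        return self.labels.reindex(self.data.columns).to_numpy()

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], self.labels)


def _resolve_duplicates(df: pd.DataFrame, policy: str) -> pd.DataFrame:
    if not df.index.has_duplicates:
        return df
    if policy == "mean":
        # groupby(sort=False) keeps first-occurrence order
        return df.groupby(level=0, sort=False).mean()
    if policy == "max-variance":
        var = df.var(axis=1, ddof=1).to_numpy()
        keep = np.zeros(len(df), dtype=bool)
        order = pd.Series(np.arange(len(df)), index=df.index)
        for _gene, idx in order.groupby(level=0, sort=False):
            pos = idx.to_numpy()
            keep[pos[np.argmax(var[pos])]] = True
        return df.loc[keep]
    raise ValueError(f"unknown duplicate policy {policy!r}")


def read_annotations(path) -> pd.Series:
    """Read a two-column sample annotation table (sample_id, label)."""
    ann = pd.read_csv(path, sep="\t", dtype={0: str})
    if ann.shape[1] < 2:
        raise ValueError(f"annotation file {path} needs columns sample_id, label")
    ann = ann.iloc[:, :2]
    ann.columns = ["sample_id", "label"]
    if ann["sample_id"].duplicated().any():
        dup = ann.loc[ann["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"sample {dup!r} annotated more than once")
    return pd.Series(ann["label"].to_numpy(), index=ann["sample_id"], name="label")


def read_matrix(path, annotation_path=None, duplicate_policy: str = "mean") -> ExpressionMatrix:
    """Read a tab-delimited expression matrix, optionally with labels.

    The file's first column holds gene ids, the header row sample ids.
    Duplicate gene ids are resolved by ``duplicate_policy``: ``"mean"``
    (per-sample mean of the duplicate rows, order independent) or
    ``"max-variance"`` (keep the most variable row).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: malformed header, no sample columns found")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column {col!r}, "
                f"row {bad.index[0]!r}"
            )
    df = _resolve_duplicates(df, duplicate_policy)
    labels = read_annotations(annotation_path) if annotation_path is not None else None
    return ExpressionMatrix(df.astype(float), labels)


def write_matrix(matrix: ExpressionMatrix, path, float_format: str = "%.6g") -> None:
    """Write the matrix in the same TSV dialect ``read_matrix`` consumes."""
    matrix.data.to_csv(path, sep="\t", index_label="GeneID", float_format=float_format)


def log2_tpm_transform(counts) -> np.ndarray:
    """log2(x + 1) transform of non-negative abundances (TPM or similar)."""
    arr = np.asarray(counts, dtype=float)
    if arr.size and np.nanmin(arr) < 0:
        raise ValueError("negative abundance value; TPM input must be >= 0")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite abundance value")
    return np.log2(arr + 1.0)


def filter_dynamic_range(
    matrix: ExpressionMatrix, trits: "TritMatrix", min_frac: float = 0.05
) -> ExpressionMatrix:
    """Drop genes without a usable dynamic range of expression.

    A gene is retained only if at least ``min_frac`` of its samples are
    called high AND at least ``min_frac`` are called low (fractions over all
    samples, intermediates included in the denominator).  Genes that are
    nearly always low or nearly always high carry no usable Boolean signal.
    """
    if not (0.0 <= min_frac <= 0.5):
        raise ValueError("min_frac must be in [0, 0.5]")
    if list(trits.gene_ids) != list(matrix.gene_ids):
        raise ValueError("gene sets of matrix and trits differ")
    t = trits.trits
    n = t.shape[1]
    frac_low = (t == 0).sum(axis=1) / n
    frac_high = (t == 2).sum(axis=1) / n
    keep = (frac_low >= min_frac) & (frac_high >= min_frac)
    kept_genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return matrix.subset_genes(kept_genes)
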