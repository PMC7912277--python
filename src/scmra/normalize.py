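"""Count normalization and gene filtering.

Two normalizations are used in different parts of the pipeline: length-aware
TPM (transcripts per kilobase million) for display, correlation and
pseudobulk work, and Seurat-style LogNormalize (ln(1 + count/colsum * 1e4))
for differential expression and module scoring. Gene filtering removes genes
detected (count > 0) in fewer than ``min_cells`` cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExprMatrix, TPM_TOTAL, ValidationError

__all__ = ["tpm", "log10_with_pseudo", "lognormalize", "filter_genes", "DEFAULT_PSEUDO"]

#: Pseudocount added to TPM before log10 so that undetected genes map to -4.
DEFAULT_PSEUDO = 1e-4


def _check_nonzero_cells(counts: pd.DataFrame) -> None:
    colsum = counts.to_numpy().sum(axis=0)
    zero = np.flatnonzero(colsum == 0)
    if zero.size:
        names = list(counts.columns[zero[:10]])
        raise ValidationError(f"cells with zero total counts: {names}")


def tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> ExprMatrix:
    """TPM-normalize a genes x cells count matrix.

    Per cell, counts are divided by gene length in kilobases, then rescaled
    so the column sums to 1e6.

    Parameters
    ----------
    counts
        Non-negative integer genes x cells matrix.
    gene_lengths
        Gene length in base pairs, indexed by gene; every matrix gene must be
        present.
    """
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        raise ValidationError(f"genes without length annotation: {list(missing[:10])}")
    _check_nonzero_cells(counts)
    len_kb = gene_lengths.reindex(counts.index).to_numpy(float) / 1e3
    if (len_kb <= 0).any():
        raise ValidationError("gene lengths must be positive")
    rate = counts.to_numpy(float) / len_kb[:, None]
    vals = rate / rate.sum(axis=0, keepdims=True) * TPM_TOTAL
    return ExprMatrix(pd.DataFrame(vals, index=counts.index, columns=counts.columns), "TPM")


def log10_with_pseudo(x: ExprMatrix, pseudo: float = DEFAULT_PSEUDO) -> ExprMatrix:
    """log10(TPM + pseudo); with the default pseudocount a zero TPM maps to -4."""
    x.require_unit("TPM")
    vals = np.log10(x.values.to_numpy() + pseudo)
    return ExprMatrix(pd.DataFrame(vals, index=x.genes, columns=x.cells), "log10TPM")


def lognormalize(counts: pd.DataFrame, scale: float = 1e4) -> ExprMatrix:
    """Seurat LogNormalize: ln(1 + count / colsum * scale)."""
    _check_nonzero_cells(counts)
    arr = counts.to_numpy(float)
    vals = np.log1p(arr / arr.sum(axis=0, keepdims=True) * scale)
    return ExprMatrix(pd.DataFrame(vals, index=counts.index, columns=counts.columns), "lognorm")


def filter_genes(counts: pd.DataFrame, min_cells: int = 3) -> pd.DataFrame:
    """Drop genes detected (count > 0) in fewer than *min_cells* cells.

    A gene detected in exactly *min_cells* cells is retained; gene order is
    preserved. ``min_cells=0`` is the identity.
    """
    detected = (counts.to_numpy() > 0).sum(axis=1)
    return counts.loc[detected >= min_cells]
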