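"""Pseudobulk aggregation and Spearman matching against bulk panels.

Summing TPM across single cells and rescaling to 1e6 yields a pseudobulk
profile directly comparable to a TPM-normalized bulk RNA-seq sample; the
cell line of origin is then identified as the panel sample with the highest
Spearman correlation.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd
import scipy.stats

from .containers import ExprMatrix, TPM_TOTAL, ValidationError
from .normalize import DEFAULT_PSEUDO

__all__ = ["pseudobulk", "match_bulk", "MIN_SHARED_GENES"]

MIN_SHARED_GENES = 100


def pseudobulk(x: ExprMatrix) -> pd.Series:
    """Sum TPM across cells and rescale to a 1e6-total profile."""
    x.require_unit("TPM")
    if x.values.shape[1] < 1:
        raise ValidationError("pseudobulk needs at least one cell")
    total = x.values.sum(axis=1)
    return total / total.sum() * TPM_TOTAL


def match_bulk(
    pb: Union[pd.Series, pd.DataFrame],
    panel: pd.DataFrame,
    pseudo: float = DEFAULT_PSEUDO,
) -> pd.DataFrame:
    """Spearman-correlate pseudobulk profile(s) against a bulk panel.

    Both sides must be TPM-scaled, genes on the index. Correlations are
    computed on log10(TPM + pseudo) over the gene intersection (at least
    100 shared genes); since Spearman is rank-based the log transform does
    not change the coefficients, only the scale on which profiles would be
    plotted. Returns a table with one row per (pseudobulk, sample) pair,
    sorted within each pseudobulk by descending rho (ties broken by sample
    label), with the best match flagged.
    """
    if isinstance(pb, pd.Series):
        pb = pb.to_frame(pb.name if pb.name is not None else "pseudobulk")
    shared = pb.index.intersection(panel.index)
    if len(shared) < MIN_SHARED_GENES:
        raise ValidationError(
            f"only {len(shared)} shared genes between pseudobulk and panel "
            f"(need >= {MIN_SHARED_GENES})"
        )
    a = np.log10(pb.loc[shared].to_numpy(float) + pseudo)
    b = np.log10(panel.loc[shared].to_numpy(float) + pseudo)
    rows = []
    for i, pb_name in enumerate(pb.columns):
        for j, sample in enumerate(panel.columns):
            rho = scipy.stats.spearmanr(a[:, i], b[:, j]).statistic
            rows.append((pb_name, sample, float(rho)))
    table = pd.DataFrame(rows, columns=["pseudobulk", "sample", "rho"])
    table = table.sort_values(
        ["pseudobulk", "rho", "sample"], ascending=[True, False, True], ignore_index=True
    )
    table["rank"] = table.groupby("pseudobulk").cumcount() + 1
    table["best_match"] = table["rank"] == 1
    return table
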