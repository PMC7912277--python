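"""Per-gene summary statistics and two-group differential expression.

The mean-variance analysis works on log10 TPM: the raw expression variance
of a gene is dominated by its mean, so the quantity of interest is the
*residual* variance after removing the mean trend with a loess regression
(local quadratic, tricube weights). Differential expression between two cell
groups uses the Wilcoxon rank-sum test per gene on LogNormalized values with
Benjamini-Hochberg correction, and the resulting table is collapsed into a
signed-z signature for enrichment analysis.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import ExprMatrix, ValidationError

__all__ = [
    "loess_fit",
    "gene_stats",
    "wilcoxon_de",
    "benjamini_hochberg",
    "group_signature",
]

#: p-value floor preventing infinite z-scores in signatures.
P_FLOOR = 1e-300

#: Largest group size for which the exact (tie-free) Wilcoxon null is used.
_EXACT_MAX_N = 25


def loess_fit(
    x: np.ndarray, y: np.ndarray, span: float = 0.3, degree: int = 2
) -> np.ndarray:
    """Loess-smooth y on x and return fitted values at each x.

    Local polynomial regression of the given degree with tricube weights
    over the ``ceil(span * n)`` nearest neighbours of each point (no
    robustness iterations). With ``degree=2`` an exactly-quadratic trend is
    reproduced to machine precision.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    fitted_sorted = np.empty(n)
    lo = 0
    for i in range(n):
        # slide the k-window to the neighbourhood of xs[i]
        while lo + k < n and xs[lo + k] - xs[i] < xs[i] - xs[lo]:
            lo += 1
        xw = xs[lo : lo + k]
        yw = ys[lo : lo + k]
        d = np.abs(xw - xs[i])
        dmax = d.max()
        if dmax == 0:
            fitted_sorted[i] = yw.mean()
            continue
        w = (1 - np.clip(d / dmax, 0, 1) ** 3) ** 3
        w = np.maximum(w, 1e-12)
        coeffs = np.polyfit(xw - xs[i], yw, deg=degree, w=np.sqrt(w))
        fitted_sorted[i] = coeffs[-1]  # polynomial evaluated at the centre
    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    return fitted


def gene_stats(
    x: ExprMatrix, counts: pd.DataFrame, span: float = 0.3, degree: int = 2
) -> pd.DataFrame:
    """Per-gene mean, variance, loess-residual variance and detection rate.

    Parameters
    ----------
    x
        log10 TPM expression matrix (genes x cells).
    counts
        Raw counts on the same gene/cell index, used for the detection
        fraction (count > 0).

    Returns
    -------
    DataFrame indexed by gene with columns ``mean``, ``variance``,
    ``residual_variance`` and ``detection_fraction``. The residual variance
    is ``variance - loess_fit(mean)``, removing the mean-expression trend
    that would otherwise dominate any variance ranking.
    """
    x.require_unit("log10TPM")
    if not x.genes.equals(counts.index) or not x.cells.equals(counts.columns):
        raise ValidationError("expression and count matrices must share gene/cell indices")
    if len(x.genes) < 10:
        raise ValidationError("loess trend needs at least 10 genes")
    arr = x.values.to_numpy()
    mean = arr.mean(axis=1)
    var = arr.var(axis=1, ddof=1) if arr.shape[1] > 1 else np.zeros(len(mean))
    trend = loess_fit(mean, var, span=span, degree=degree)
    det = (counts.to_numpy() > 0).mean(axis=1)
    return pd.DataFrame(
        {
            "mean": mean,
            "variance": var,
            "residual_variance": var - trend,
            "detection_fraction": det,
        },
        index=x.genes,
    )


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, float)
    if p.size and (np.isnan(p).any() or p.min() < 0 or p.max() > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _rank_sum_asymptotic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided tie-corrected Wilcoxon rank-sum over gene rows."""
    n1, n2 = a.shape[1], b.shape[1]
    pooled = np.concatenate([a, b], axis=1)
    ranks = scipy.stats.rankdata(pooled, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction: sum of t^3 - t over tied groups, per gene
    srt = np.sort(pooled, axis=1)
    n = n1 + n2
    tie_term = np.zeros(len(pooled))
    for g in range(len(pooled)):
        _, cnt = np.unique(srt[g], return_counts=True)
        tie_term[g] = (cnt**3 - cnt).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u1 - mu - np.sign(u1 - mu) * 0.5) / np.sqrt(sigma2)
        pvals = 2 * scipy.stats.norm.sf(np.abs(z))
    pvals = np.where(sigma2 <= 0, 1.0, pvals)  # all-tied gene: no evidence
    return np.minimum(pvals, 1.0)


def wilcoxon_de(a: ExprMatrix | pd.DataFrame, b: ExprMatrix | pd.DataFrame) -> pd.DataFrame:
    """Two-group differential expression, gene by gene.

    *a* and *b* are LogNormalized genes x cells matrices (group A and B)
    sharing the gene index; each group needs at least 3 cells. The test is
    the two-sided Wilcoxon rank-sum test: exact null when both groups are
    small and the gene has no ties, tie-corrected normal approximation
    otherwise. A gene tied across every cell of both groups gets p = 1.

    Returns a DataFrame sorted by p-value with columns ``gene``,
    ``p_value``, ``avg_logFC`` (natural log, A minus B), ``pct_1``/``pct_2``
    (detection fraction per group) and ``adj_p`` (Benjamini-Hochberg over
    all tested genes).
    """
    a_df = a.require_unit("lognorm").values if isinstance(a, ExprMatrix) else a
    b_df = b.require_unit("lognorm").values if isinstance(b, ExprMatrix) else b
    if not a_df.index.equals(b_df.index):
        raise ValidationError("groups must share the gene index")
    if a_df.shape[1] < 3 or b_df.shape[1] < 3:
        raise ValidationError("each group needs at least 3 cells")
    av, bv = a_df.to_numpy(float), b_df.to_numpy(float)

    if max(av.shape[1], bv.shape[1]) <= _EXACT_MAX_N:
        pvals = np.empty(len(av))
        for g in range(len(av)):
            row = np.concatenate([av[g], bv[g]])
            if np.all(row == row[0]):
                pvals[g] = 1.0
                continue
            has_ties = len(np.unique(row)) < len(row)
            method = "asymptotic" if has_ties else "exact"
            pvals[g] = scipy.stats.mannwhitneyu(
                av[g], bv[g], alternative="two-sided", method=method
            ).pvalue
    else:
        pvals = _rank_sum_asymptotic(av, bv)

    logfc = np.log(np.expm1(av).mean(axis=1) + 1) - np.log(np.expm1(bv).mean(axis=1) + 1)
    out = pd.DataFrame(
        {
            "gene": a_df.index,
            "p_value": pvals,
            "avg_logFC": logfc,
            "pct_1": (av > 0).mean(axis=1),
            "pct_2": (bv > 0).mean(axis=1),
            "adj_p": benjamini_hochberg(pvals),
        }
    )
    return out.sort_values("p_value", kind="mergesort", ignore_index=True)


def group_signature(de: pd.DataFrame) -> pd.Series:
    """Collapse a DE table into a signed-z per-gene signature.

    score = sign(avg_logFC) * |Phi^-1(p/2)| with p floored at 1e-300, so a
    gene up in group A gets a positive score whose magnitude grows as p
    shrinks. This puts all genes on a common normal scale regardless of
    their expression level, which keeps permutation nulls comparable.
    """
    if len(de) == 0:
        raise ValidationError("empty DE table")
    p = np.maximum(de["p_value"].to_numpy(float), P_FLOOR)
    z = scipy.stats.norm.isf(p / 2.0)
    score = np.sign(de["avg_logFC"].to_numpy(float)) * np.abs(z)
    sig = pd.Series(score, index=pd.Index(de["gene"], name="gene"), name="score")
    if not sig.index.is_unique:
        raise ValidationError("duplicate genes in DE table")
    return sig
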