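"""Per-cell signatures, activity matrices and cell-cycle phase calls.

A single cell's signature is its z-scored deviation from the dataset mean,
gene by gene. Scoring each cell signature against regulons or gene sets
yields a cells x objects NES activity matrix (single-cell MRA / GSEA);
the permutation null per object is shared across cells so the per-cell NES
values are on a common scale. Cell-cycle phases are called from
expression-matched module scores of S and G2/M gene programs: a cell with
both scores negative is in G1, otherwise the larger score wins.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .containers import ExprMatrix, Regulon, ValidationError
from .enrichment import DEFAULT_MIN_SIZE, _es_from_positions

__all__ = [
    "cell_signatures",
    "sc_activity",
    "cc_scores",
    "assign_phase",
    "phase_fractions",
]

PHASES = ("G1", "S", "G2M")

#: Variance floor preventing division blow-ups in near-constant genes.
SD_FLOOR = 1e-8


def cell_signatures(x: Union[ExprMatrix, pd.DataFrame]) -> pd.DataFrame:
    """Z-score each cell against the dataset mean, per gene.

    score[g, c] = (x[g, c] - mean_g) / sd_g with population (divisor n)
    standard deviation floored at 1e-8; genes constant across the dataset
    carry no between-cell information and are dropped. Columns are per-cell
    signatures.
    """
    vals = x.require_unit("log10TPM").values if isinstance(x, ExprMatrix) else x
    if vals.shape[1] < 2:
        raise ValidationError("per-cell signatures need at least 2 cells")
    arr = vals.to_numpy(float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0)
    keep = sd > 0
    z = (arr[keep] - mean[keep]) / np.maximum(sd[keep], SD_FLOOR)[:, None]
    return pd.DataFrame(z, index=vals.index[keep], columns=vals.columns)


def _normalize_objects(objs) -> List[Tuple[str, object]]:
    if isinstance(objs, dict):
        return list(objs.items())
    out = []
    for obj in objs:
        if isinstance(obj, Regulon):
            out.append((obj.tf, obj))
        else:
            raise ValidationError("objs must be Regulons or a {name: genes} mapping")
    return out


def sc_activity(
    x: Union[ExprMatrix, pd.DataFrame],
    objs,
    n_perm: int = 100,
    seed: Optional[int] = None,
    min_size: int = DEFAULT_MIN_SIZE,
) -> pd.DataFrame:
    """Per-cell NES activity matrix (cells x regulons/sets).

    *x* is either a log10 TPM matrix or a precomputed signature DataFrame
    from :func:`cell_signatures`. For each object the enrichment score of
    every cell signature is normalized against one shared null pool: the
    scores of ``n_perm`` seeded gene-label permutations evaluated against
    every cell, pooled. Sharing the pool keeps cells comparable; the same
    permutations drive every object.
    """
    if isinstance(x, ExprMatrix):
        sigs = cell_signatures(x)
    else:
        sigs = x
    items = _normalize_objects(objs)
    if not items:
        raise ValidationError("no objects to score")
    genes = sigs.index
    loc = {g: i for i, g in enumerate(genes)}
    arr = sigs.to_numpy(float)
    n_genes, n_cells = arr.shape

    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n_genes) for _ in range(n_perm)]

    # per-cell descending-score rankings, needed only for gene-set objects
    rank_desc = None
    if any(not isinstance(obj, Regulon) for _, obj in items):
        rank_desc = np.empty((n_genes, n_cells), dtype=np.intp)
        gene_arr = genes.to_numpy(dtype=object)
        for c in range(n_cells):
            order = np.lexsort((gene_arr, -arr[:, c]))
            rank_desc[order, c] = np.arange(n_genes)

    out = {}
    for name, obj in items:
        if isinstance(obj, Regulon):
            sub = obj.restrict(genes)
            if len(sub) < min_size:
                raise ValidationError(
                    f"regulon {name}: {len(sub)} targets in universe, below min_size={min_size}"
                )
            idx = np.array([loc[t] for t in sub.targets], dtype=np.intp)
            w = sub.likelihoods * sub.modes / sub.likelihoods.sum()
            es_obs = w @ arr[idx]  # (n_cells,)
            null = np.stack([w @ arr[p[idx]] for p in perms])  # (n_perm, n_cells)
        else:
            present = np.array([loc[g] for g in obj if g in loc], dtype=np.intp)
            if len(present) < min_size:
                raise ValidationError(
                    f"gene set {name}: {len(present)} genes in universe, below min_size={min_size}"
                )
            es_obs = np.empty(n_cells)
            null = np.empty((n_perm, n_cells))
            for c in range(n_cells):
                abs_ranked = np.abs(arr[:, c])[np.argsort(rank_desc[:, c])]
                es_obs[c] = _es_from_positions(abs_ranked, rank_desc[present, c])
                for i, p in enumerate(perms):
                    null[i, c] = _es_from_positions(abs_ranked, rank_desc[p[present], c])
        pool = null.ravel()
        pos_mean = np.abs(pool[pool > 0]).mean() if (pool > 0).any() else np.abs(pool).mean()
        neg_mean = np.abs(pool[pool < 0]).mean() if (pool < 0).any() else np.abs(pool).mean()
        denom = np.where(es_obs >= 0, pos_mean, neg_mean)
        if np.all(pool == 0):
            raise ValidationError(f"object {name}: degenerate permutation null")
        out[name] = es_obs / denom

    return pd.DataFrame(out, index=sigs.columns)


def cc_scores(
    x: Union[ExprMatrix, pd.DataFrame],
    s_genes: Sequence[str],
    g2m_genes: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Expression-matched S and G2/M module scores per cell.

    For each phase list the score is the mean LogNormalized expression of
    the list genes minus that of a control pool: per list gene, ``n_ctrl``
    genes drawn from the same dataset-mean expression bin (genes cut into
    ``n_bins`` rank bins). The matching cancels depth and mean-expression
    effects, so an unexpressed program scores near (or below) zero.
    """
    vals = x.require_unit("lognorm").values if isinstance(x, ExprMatrix) else x
    gene_means = vals.mean(axis=1)
    ranks = gene_means.rank(method="first")
    bins = pd.cut(ranks, bins=n_bins, labels=False)
    rng = np.random.default_rng(seed)

    def module_score(gene_list: Sequence[str], label: str) -> np.ndarray:
        present = [g for g in gene_list if g in vals.index]
        if len(present) < 5:
            raise ValidationError(
                f"{label}: only {len(present)} of {len(gene_list)} genes present (need >= 5)"
            )
        listed = set(present)
        # one control average per list gene, so bins with several list genes
        # carry proportional weight in the control term
        ctrl_means = []
        for g in sorted(present):  # sorted so scores don't depend on list order
            bin_id = bins.loc[g]
            pool = bins.index[(bins == bin_id).to_numpy() & ~bins.index.isin(listed)]
            if len(pool) == 0:
                continue
            take = rng.choice(len(pool), size=min(n_ctrl, len(pool)), replace=False)
            ctrl_means.append(vals.loc[pool[take]].to_numpy().mean(axis=0))
        if not ctrl_means:
            raise ValidationError(f"{label}: no control genes available")
        list_mean = vals.loc[sorted(listed)].to_numpy().mean(axis=0)
        return list_mean - np.mean(ctrl_means, axis=0)

    return pd.DataFrame(
        {
            "s_score": module_score(s_genes, "S gene list"),
            "g2m_score": module_score(g2m_genes, "G2M gene list"),
        },
        index=vals.columns,
    )


def assign_phase(scores: pd.DataFrame) -> pd.DataFrame:
    """Call G1/S/G2M per cell from module scores.

    G1 iff both scores are negative; otherwise the phase with the larger
    score. Returns the input scores plus a ``phase`` column.
    """
    s = scores["s_score"].to_numpy(float)
    g2m = scores["g2m_score"].to_numpy(float)
    phase = np.where((s < 0) & (g2m < 0), "G1", np.where(s >= g2m, "S", "G2M"))
    out = scores.copy()
    out["phase"] = phase
    return out


def phase_fractions(calls: pd.DataFrame, populations: pd.Series) -> pd.DataFrame:
    """Per-population phase-fraction table (rows sum to 1)."""
    df = calls.join(populations.rename("population"))
    tab = (
        df.groupby("population")["phase"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(PHASES), fill_value=0.0)
    )
    tab.columns.name = None
    return tab
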