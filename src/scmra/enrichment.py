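"""Gene-set and regulon enrichment with permutation-based NES.

This is the analytical core of the package. A *signature* (per-gene signed
scores, e.g. the signed-z of a two-group contrast) is interrogated with
either gene sets (classic weighted-KS GSEA enrichment score) or regulons
(likelihood-weighted, mode-signed mean of target scores). Significance comes
from a permutation null: shuffling the signature's gene labels
(``gene_shuffle``), re-deriving the signature after permuting the group
labels of the underlying expression matrix (``sample_shuffle``), or
alternating the two (``both``). The observed enrichment score is normalized
by the mean magnitude of same-sign permuted scores, giving the normalized
enrichment score (NES) used to rank master regulators.

The batch analyses are exposed as model objects —
:class:`MasterRegulatorAnalysis` and :class:`GeneSetEnrichment` — whose
``fit`` returns an :class:`EnrichmentResults` carrying ES/NES estimates,
permutation p-values, BH FDR and a ``summary()`` table; ``mra`` and
``gsea_batch`` are functional wrappers over them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .containers import EnrichmentResult, ExprMatrix, Regulon, ValidationError
from .exprstats import benjamini_hochberg, group_signature, wilcoxon_de

__all__ = [
    "gsea_es",
    "regulon_es",
    "permutation_null",
    "nes",
    "mra",
    "gsea_batch",
    "MasterRegulatorAnalysis",
    "GeneSetEnrichment",
    "EnrichmentResults",
    "DEFAULT_MIN_SIZE",
]

logger = logging.getLogger(__name__)

#: Minimum targets/genes (after intersection with the signature universe)
#: for a regulon or gene set to be scored; enrichment on tiny sets is noise.
DEFAULT_MIN_SIZE = 10

SCHEMES = ("gene_shuffle", "sample_shuffle", "both")


# ---------------------------------------------------------------------------
# Ranking and enrichment scores
# ---------------------------------------------------------------------------

def _ranked(sig: pd.Series) -> Tuple[np.ndarray, np.ndarray]:
    """Genes and scores sorted by descending score, ties by gene id."""
    genes = sig.index.to_numpy(dtype=object)
    scores = sig.to_numpy(float)
    order = np.lexsort((genes, -scores))
    return genes[order], scores[order]


def _es_from_positions(ranked_abs_pow: np.ndarray, positions: np.ndarray) -> float:
    """Weighted-KS enrichment score given sorted 0-based hit positions.

    The running sum increments at hit j by its normalized weight and
    decrements by 1/(N-k) at every miss; its extrema can only occur
    immediately before or after a hit, so only those 2k candidates are
    evaluated.
    """
    positions = np.sort(np.asarray(positions))
    k = len(positions)
    n = len(ranked_abs_pow)
    if k == 0:
        raise ValidationError("gene set has no gene in the signature universe")
    if k >= n:
        raise ValidationError("gene set must be smaller than the signature universe")
    w = ranked_abs_pow[positions]
    tot = w.sum()
    w = w / tot if tot > 0 else np.full(k, 1.0 / k)
    hits = np.cumsum(w)
    miss = 1.0 / (n - k)
    misses_so_far = positions - np.arange(k)
    after = hits - misses_so_far * miss
    before = after - w
    # walk order (before each hit, then after it) so that an exact tie in
    # magnitude resolves to the extreme reached first, as in the raw walk
    cands = np.empty(2 * k)
    cands[0::2] = before
    cands[1::2] = after
    return float(cands[np.argmax(np.abs(cands))])


def gsea_es(sig: pd.Series, genes: Sequence[str], weight: float = 1.0) -> float:
    """Classic GSEA enrichment score of *genes* against *sig*.

    Genes are ranked by descending signature score (ties broken by gene id);
    the running sum gains ``|score|^weight`` (normalized over the set) at
    each set gene and loses ``1/(N - n_set)`` elsewhere. The ES is the
    signed maximal deviation of this walk from zero.
    """
    ranked_genes, ranked_scores = _ranked(sig)
    gene_set = set(genes)
    n = len(ranked_genes)
    hit = np.fromiter((g in gene_set for g in ranked_genes), bool, n)
    k = int(hit.sum())
    if k == 0:
        raise ValidationError(f"no gene of the set is in the signature universe: {sorted(gene_set)[:5]}...")
    if k >= n:
        raise ValidationError("gene set must be smaller than the signature universe")
    abs_pow = np.abs(ranked_scores) ** weight
    tot = 0.0
    for v in abs_pow[hit]:  # left-to-right, exactly as the definition sums
        tot += v
    steps = np.where(hit, abs_pow / tot if tot > 0 else 1.0 / k, -(1.0 / (n - k)))
    cum = np.cumsum(steps)
    return float(cum[np.argmax(np.abs(cum))])


def regulon_es(sig: pd.Series, regulon: Regulon, min_size: int = DEFAULT_MIN_SIZE) -> float:
    """Likelihood-weighted, mode-signed mean of regulon target scores.

    ES = sum_t likelihood_t * mode_t * sig[target_t] / sum_t likelihood_t
    over the targets present in the signature universe. Linear in the
    signature; positive when mode=+1 targets score high and mode=-1 targets
    score low (the TF's program is up).
    """
    sub = regulon.restrict(sig.index)
    if len(sub) < min_size:
        raise ValidationError(
            f"regulon {regulon.tf}: {len(sub)} targets in universe, below min_size={min_size}"
        )
    scores = sig.reindex(sub.targets.astype(str)).to_numpy(float)
    return float((sub.likelihoods * sub.modes * scores).sum() / sub.likelihoods.sum())


# ---------------------------------------------------------------------------
# Permutation nulls and NES
# ---------------------------------------------------------------------------

def _obj_es(sig: pd.Series, obj, min_size: int, weight: float) -> float:
    if isinstance(obj, Regulon):
        return regulon_es(sig, obj, min_size=min_size)
    return gsea_es(sig, obj, weight=weight)


def _sample_shuffle_signature(
    expr_a: pd.DataFrame, expr_b: pd.DataFrame, rng: np.random.Generator
) -> pd.Series:
    pooled = pd.concat([expr_a, expr_b], axis=1)
    n_a = expr_a.shape[1]
    perm = rng.permutation(pooled.shape[1])
    de = wilcoxon_de(pooled.iloc[:, perm[:n_a]], pooled.iloc[:, perm[n_a:]])
    return group_signature(de)


def _as_frame(expr) -> pd.DataFrame:
    return expr.values if isinstance(expr, ExprMatrix) else expr


def permutation_null(
    sig: pd.Series,
    obj: Union[Regulon, Sequence[str]],
    n_perm: int = 1000,
    scheme: str = "gene_shuffle",
    seed: Optional[int] = None,
    expr_a=None,
    expr_b=None,
    min_size: int = DEFAULT_MIN_SIZE,
    weight: float = 1.0,
) -> np.ndarray:
    """Null enrichment scores of *obj* under the chosen permutation scheme.

    ``gene_shuffle`` permutes the signature's gene labels, randomizing which
    genes the set/regulon points at; ``sample_shuffle`` recomputes the
    signature after permuting the group labels of the supplied two-group
    expression matrices; ``both`` alternates the two schemes permutation by
    permutation.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    if n_perm < 10:
        raise ValidationError("n_perm must be at least 10")
    if scheme in ("sample_shuffle", "both") and (expr_a is None or expr_b is None):
        raise ValidationError(
            f"scheme {scheme!r} requires the two-group expression context (expr_a, expr_b)"
        )
    rng = np.random.default_rng(seed)
    genes = sig.index
    scores = sig.to_numpy(float)
    plan = _ShufflePlan(sig, [("", obj)], min_size, weight)
    out = np.empty(n_perm)
    for i in range(n_perm):
        use_sample = scheme == "sample_shuffle" or (scheme == "both" and i % 2 == 1)
        if use_sample:
            perm_sig = _sample_shuffle_signature(_as_frame(expr_a), _as_frame(expr_b), rng)
            perm_sig = perm_sig.reindex(genes).fillna(0.0)
            out[i] = _obj_es(perm_sig, obj, min_size, weight)
        else:
            out[i] = plan.es_under(rng.permutation(len(scores)))[0]
    return out


class _ShufflePlan:
    """Precomputed indices for fast gene-shuffle null scores.

    Shuffling the signature's gene labels leaves the multiset of scores (and
    hence the ranked score weights) fixed; only which gene sits at which
    rank changes. One uniform random permutation therefore drives the null
    ES of every object within a permutation, keeping them comparable.
    """

    def __init__(self, sig: pd.Series, objs, min_size: int, weight: float):
        genes = sig.index
        self.scores = sig.to_numpy(float)
        loc = {g: i for i, g in enumerate(genes)}
        order = np.lexsort((genes.to_numpy(dtype=object), -self.scores))
        # rank_desc[j]: ranked position of the score held by universe index j
        self.rank_desc = np.empty(len(order), dtype=np.intp)
        self.rank_desc[order] = np.arange(len(order))
        self.ranked_abs_pow = np.abs(self.scores[order]) ** weight
        self.items = []  # (is_regulon, idx, signed weights or None)
        for _, obj in objs:
            if isinstance(obj, Regulon):
                sub = obj.restrict(genes)
                idx = np.array([loc[t] for t in sub.targets], dtype=np.intp)
                w = sub.likelihoods * sub.modes / sub.likelihoods.sum()
                self.items.append((True, idx, w))
            else:
                idx = np.array([loc[g] for g in obj if g in loc], dtype=np.intp)
                self.items.append((False, idx, None))

    def es_under(self, perm: np.ndarray) -> np.ndarray:
        s_perm = self.scores[perm]
        out = np.empty(len(self.items))
        for j, (is_reg, idx, w) in enumerate(self.items):
            if is_reg:
                out[j] = float(w @ s_perm[idx])
            else:
                out[j] = _es_from_positions(self.ranked_abs_pow, self.rank_desc[perm[idx]])
        return out


def nes(es_obs: float, null: Sequence[float]) -> Tuple[float, float]:
    """Normalized enrichment score and permutation p-value.

    NES divides the observed ES by the mean |ES| of same-sign permutations
    (falling back to all permutations when no same-sign one exists); a raw
    mean over signed permutation scores would sit near zero and be
    numerically unstable. p uses the add-one estimator on |ES| exceedance,
    so p >= 1/(n_perm + 1).
    """
    null = np.asarray(null, float)
    if null.size == 0:
        raise ValidationError("empty permutation null")
    if np.all(null == 0):
        raise ValidationError("degenerate permutation null (all zero)")
    if es_obs == 0:
        denom_pool = np.abs(null)
    else:
        same = null * np.sign(es_obs) > 0
        denom_pool = np.abs(null[same]) if same.any() else np.abs(null)
    denom = denom_pool.mean()
    nes_val = es_obs / denom
    p = (1.0 + np.sum(np.abs(null) >= abs(es_obs))) / (null.size + 1.0)
    return float(nes_val), float(p)


# ---------------------------------------------------------------------------
# Batch model objects
# ---------------------------------------------------------------------------

class EnrichmentResults:
    """Fitted enrichment results, sorted by NES descending.

    Attributes
    ----------
    frame : DataFrame with columns name, es, nes, p_value, fdr, n_perm,
        direction.
    results : list of :class:`EnrichmentResult` in the same order.
    """

    def __init__(self, results: List[EnrichmentResult], kind: str):
        self.results = sorted(results, key=lambda r: -r.nes)
        self.kind = kind
        self.frame = pd.DataFrame(
            {
                "name": [r.name for r in self.results],
                "es": [r.es for r in self.results],
                "nes": [r.nes for r in self.results],
                "p_value": [r.p_value for r in self.results],
                "fdr": [r.fdr for r in self.results],
                "n_perm": [r.n_perm for r in self.results],
                "direction": [r.direction for r in self.results],
            }
        )

    def top(self, n: int = 10) -> pd.DataFrame:
        """Top *n* up- and down-regulated entries (the two-panel layout)."""
        return pd.concat([self.frame.head(n), self.frame.tail(n)]).drop_duplicates("name")

    def summary(self) -> str:
        lines = [
            f"{self.kind} enrichment results",
            f"  objects scored: {len(self.frame)}",
            "",
            self.frame.to_string(
                index=False,
                float_format=lambda v: f"{v: .4g}",
            ),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<EnrichmentResults: {len(self.frame)} {self.kind} objects>"


class _EnrichmentModel:
    """Shared fitting machinery for regulon and gene-set batch enrichment."""

    kind = "enrichment"

    def __init__(self, signature: pd.Series, min_size: int = DEFAULT_MIN_SIZE):
        if not isinstance(signature, pd.Series):
            signature = pd.Series(signature)
        if not signature.index.is_unique:
            raise ValidationError("signature gene ids must be unique")
        if not np.all(np.isfinite(signature.to_numpy(float))):
            raise ValidationError("signature scores must be finite")
        self.signature = signature.astype(float)
        self.min_size = min_size

    # subclasses supply the eligible (name, obj) pairs
    def _objects(self) -> List[Tuple[str, object]]:  # pragma: no cover - abstract
        raise NotImplementedError

    def _weight(self) -> float:
        return 1.0

    def fit(
        self,
        n_perm: int = 1000,
        seed: Optional[int] = None,
        scheme: Optional[str] = None,
        expr_a=None,
        expr_b=None,
    ) -> EnrichmentResults:
        """Score every eligible object and normalize against a shared null.

        One permuted signature per permutation is shared across all objects
        so their null scores are comparable within a permutation. *scheme*
        defaults to ``both`` when the two-group expression context is given
        and ``gene_shuffle`` otherwise.
        """
        if scheme is None:
            scheme = "both" if expr_a is not None and expr_b is not None else "gene_shuffle"
        if scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {scheme!r}")
        if scheme in ("sample_shuffle", "both") and (expr_a is None or expr_b is None):
            raise ValidationError(
                f"scheme {scheme!r} requires the two-group expression context"
            )
        objs = self._objects()
        if not objs:
            raise ValidationError("no eligible object meets min_size in the signature universe")
        weight = self._weight()
        sig = self.signature
        genes = sig.index
        scores = sig.to_numpy(float)
        rng = np.random.default_rng(seed)

        es_obs = {name: _obj_es(sig, obj, self.min_size, weight) for name, obj in objs}
        plan = _ShufflePlan(sig, objs, self.min_size, weight)
        null_mat = np.empty((n_perm, len(objs)))
        for i in range(n_perm):
            use_sample = scheme == "sample_shuffle" or (scheme == "both" and i % 2 == 1)
            if use_sample:
                perm_sig = _sample_shuffle_signature(
                    _as_frame(expr_a), _as_frame(expr_b), rng
                ).reindex(genes).fillna(0.0)
                null_mat[i] = [
                    _obj_es(perm_sig, obj, self.min_size, weight) for _, obj in objs
                ]
            else:
                null_mat[i] = plan.es_under(rng.permutation(len(scores)))

        results = []
        for j, (name, _) in enumerate(objs):
            nes_val, p = nes(es_obs[name], null_mat[:, j])
            results.append(
                EnrichmentResult(name=name, es=es_obs[name], nes=nes_val, p_value=p, n_perm=n_perm)
            )
        fdr = benjamini_hochberg([r.p_value for r in results])
        for r, q in zip(results, fdr):
            r.fdr = float(q)
        return EnrichmentResults(results, self.kind)


class MasterRegulatorAnalysis(_EnrichmentModel):
    """Rank transcription factors by regulon enrichment in a signature.

    Parameters
    ----------
    signature
        Per-gene signed scores (e.g. from
        :func:`scmra.exprstats.group_signature`); positive means up in the
        condition of interest.
    regulons
        TF regulons; those with fewer than *min_size* targets in the
        signature universe are skipped with a logged warning.
    """

    kind = "regulon"

    def __init__(self, signature, regulons: Sequence[Regulon], min_size: int = DEFAULT_MIN_SIZE):
        super().__init__(signature, min_size)
        self.regulons = list(regulons)

    def _objects(self):
        objs = []
        for r in self.regulons:
            if len(r.restrict(self.signature.index)) < self.min_size:
                logger.warning(
                    "regulon %s skipped: fewer than %d targets in universe", r.tf, self.min_size
                )
                continue
            objs.append((r.tf, r))
        return objs


class GeneSetEnrichment(_EnrichmentModel):
    """Batch GSEA of a gene-set collection against a signature."""

    kind = "gene set"

    def __init__(
        self,
        signature,
        sets: Dict[str, Sequence[str]],
        min_size: int = DEFAULT_MIN_SIZE,
        weight: float = 1.0,
    ):
        super().__init__(signature, min_size)
        self.sets = dict(sets)
        self.weight = weight

    def _weight(self) -> float:
        return self.weight

    def _objects(self):
        universe = set(self.signature.index)
        objs = []
        for name, genes in self.sets.items():
            present = [g for g in genes if g in universe]
            if len(present) < self.min_size:
                logger.warning(
                    "gene set %s skipped: %d genes in universe, below min_size=%d",
                    name, len(present), self.min_size,
                )
                continue
            if len(present) >= len(universe):
                logger.warning("gene set %s skipped: covers the whole universe", name)
                continue
            objs.append((name, present))
        return objs


def mra(
    sig: pd.Series,
    regulons: Sequence[Regulon],
    n_perm: int = 1000,
    seed: Optional[int] = None,
    min_size: int = DEFAULT_MIN_SIZE,
    scheme: Optional[str] = None,
    expr_a=None,
    expr_b=None,
) -> EnrichmentResults:
    """Master regulator analysis: per-TF ES/NES/p/FDR, sorted by NES."""
    model = MasterRegulatorAnalysis(sig, regulons, min_size=min_size)
    return model.fit(n_perm=n_perm, seed=seed, scheme=scheme, expr_a=expr_a, expr_b=expr_b)


def gsea_batch(
    sig: pd.Series,
    sets: Dict[str, Sequence[str]],
    n_perm: int = 1000,
    seed: Optional[int] = None,
    min_size: int = DEFAULT_MIN_SIZE,
    weight: float = 1.0,
    scheme: Optional[str] = None,
    expr_a=None,
    expr_b=None,
) -> EnrichmentResults:
    """Batch GSEA over a collection, with the same null machinery as mra."""
    model = GeneSetEnrichment(sig, sets, min_size=min_size, weight=weight)
    return model.fit(n_perm=n_perm, seed=seed, scheme=scheme, expr_a=expr_a, expr_b=expr_b)
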