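"""Independent brute-force oracles used to validate the implementation.

Everything here is written from the mathematical definition, step by step,
without reusing any code path from the package.
"""

from itertools import combinations

import numpy as np


def brute_gsea_es(genes, scores, gene_set, weight=1.0):
    """Weighted-KS enrichment score via the explicit running sum.

    genes/scores: parallel arrays defining the signature. The walk is taken
    over genes sorted by descending score (ties by gene id); the ES is the
    running-sum value of largest magnitude.
    """
    genes = np.asarray(genes, dtype=object)
    scores = np.asarray(scores, float)
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    in_set = [genes[i] in set(gene_set) for i in order]
    n = len(genes)
    k = sum(in_set)
    denom_hits = sum(abs(scores[i]) ** weight for i, hit in zip(order, in_set) if hit)
    running = 0.0
    best = 0.0
    for i, hit in zip(order, in_set):
        if hit:
            if denom_hits > 0:
                running += abs(scores[i]) ** weight / denom_hits
            else:
                running += 1.0 / k
        else:
            running -= 1.0 / (n - k)
        if abs(running) > abs(best):
            best = running
    return best


def brute_regulon_es(sig_map, targets, modes, likelihoods):
    """Likelihood-weighted mode-signed mean, accumulated term by term."""
    num = 0.0
    den = 0.0
    for t, mo, li in zip(targets, modes, likelihoods):
        if t in sig_map:
            num += li * mo * sig_map[t]
            den += li
    return num / den


def brute_bh(pvals):
    """BH adjusted p-values as the min-over-tail of p_(j) * m / j."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_i, i in enumerate(order, start=1):
        tail = [
            min(1.0, p[j] * m / rank_j)
            for rank_j, j in enumerate(order, start=1)
            if rank_j >= rank_i
        ]
        adj[i] = min(tail)
    return adj


def exact_rank_sum_p(a, b):
    """Exact two-sided Wilcoxon rank-sum p by enumerating all splits.

    Assumes no ties. p = probability, over all C(n1+n2, n1) assignments of
    the pooled values to group A, of a rank sum at least as extreme (in
    either direction) as the observed one.
    """
    a = list(a)
    b = list(b)
    pooled = np.asarray(a + b, float)
    assert len(np.unique(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(a)
    ranks = pooled.argsort().argsort() + 1.0
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for comb in combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total


def rank_then_pearson_spearman(x, y):
    """Spearman rho as Pearson correlation of average ties-ranked data."""
    import scipy.stats

    rx = scipy.stats.rankdata(x, method="average")
    ry = scipy.stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
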