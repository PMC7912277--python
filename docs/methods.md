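# Methods

This note records the statistical model behind each step of the pipeline,
the defaults that matter, the design choices that were genuinely open, and
what the synthetic validation does and does not establish.

## Normalization and the gene filter

TPM divides each gene's count by its transcript length in kilobases and
rescales each cell to 10⁶; it is the unit for display, correlation and
pseudobulk work because it is comparable across cells and against bulk
panels. Log display uses log₁₀(TPM + 10⁻⁴), so an undetected gene maps to
exactly −4 and the most extreme single-gene cell to ≈ 6. LogNormalize,
ln(1 + count/colsum · 10⁴) with natural log, is the unit for rank-based
testing and module scores (the Seurat convention).

"Detected" means count > 0 throughout — the gene filter keeps genes with
nonzero counts in ≥ 3 cells (a gene in exactly 3 cells stays), and the
detection fraction reported in the statistics table uses the same notion.
Cells with zero total counts are rejected with their barcodes named;
normalizing them is undefined.

## Mean–variance trend and residual variance

Expression variance on the log scale is a strong function of the mean, so
genes are ranked by the *residual* variance after fitting variance ~
loess(mean) and subtracting the fit. The loess is a local quadratic with
tricube weights over the nearest ⌈span·n⌉ points, span 0.3, no robustness
iterations. Degree 2 matters: the mean–variance trend is strongly curved,
and a local-linear fit leaves curvature in the residuals; with the
quadratic the residual variance is empirically decorrelated from the mean
(|Spearman ρ| ≈ 0.01 on default synthetic data, checked in the acceptance
script). statsmodels' lowess is degree-1 only, which is why the smoother is
implemented here. Variances use ddof = 1; the fit is O(n·k) and exact (to
machine precision) on a trend that is globally quadratic.

## Differential expression and signatures

Per gene, the two-sided Wilcoxon rank-sum test compares the LogNormalized
values of the two groups. Two regimes: when both groups have ≤ 25 cells and
the gene has no ties, the exact null distribution is used (scipy's exact
method, matching an all-splits enumeration); otherwise the tie-corrected
normal approximation with continuity correction. scRNA-seq data always has
massive zero-ties at realistic sizes, so the asymptotic branch is the
operational one; the exact branch exists so that small-sample results agree
with the enumeration definition rather than with an approximation. A gene
tied across every cell of both groups carries no evidence and is reported
with p = 1 rather than dropped, keeping the table aligned with the input
universe.

The fold change is avg_logFC = ln(mean(expm1 a)+1) − ln(mean(expm1 b)+1)
(natural log, group means on the de-logged scale), and pct_1/pct_2 are the
per-group detection fractions — the six-column table (gene, p, logFC,
pct_1, pct_2, BH-adjusted p) is the standard marker-table contract.
BH adjustment delegates to statsmodels' step-up implementation behind a
validating wrapper; tests compare it against a brute-force min-over-tail
oracle.

The group signature maps each gene to sign(logFC) · |Φ⁻¹(p/2)| with p
floored at 10⁻³⁰⁰ (avoiding infinite z). The signed-z scale was chosen over
raw logFC so that genes enter enrichment on a common, approximately normal
scale regardless of expression level; this makes gene-shuffle nulls
meaningful across the whole signature.

## Enrichment scores and the permutation NES

GSEA ES is the classic weighted-KS statistic: over genes ranked by
descending score (ties broken lexicographically by gene id for
determinism), set genes add |score|^w normalized over the set, others
subtract 1/(N−k); the ES is the running sum's value of largest magnitude,
the earliest such point on an exact tie. Weight w = 1 by default. The
implementation follows the definitional sequential walk so it agrees
bit-for-bit with a literal re-implementation; the permutation fast path
uses a closed form over hit positions (extrema can only occur adjacent to
hits), which is algebraically identical.

Regulon ES is the likelihood-weighted, mode-signed mean of target scores,
ES = Σ ℓ·m·s / Σ ℓ — linear in the signature, positive when the TF's
program is up in the contrast. Regulons or sets with fewer than 10 members
inside the signature universe are skipped in batch mode (logged) and
rejected in single-object calls: enrichment on tiny sets is noise.

Permutation schemes: `gene_shuffle` permutes the signature's gene labels
(randomizing which genes an object points at); `sample_shuffle` permutes
the group labels of the underlying expression matrix and re-derives the
whole signature (and therefore needs that context passed in); `both`
alternates them permutation by permutation. Within one permutation, a
single shuffle drives the null ES of every object, keeping the per-object
nulls comparable. When no expression context is supplied the scheme is
gene_shuffle; with context the default is `both`.

NES = ES_obs / mean(|ES_perm| over same-sign permutations), falling back to
all permutations when no same-sign one exists. A raw mean of signed
permutation scores sits near zero, which would make the ratio numerically
unstable; normalizing by the same-sign magnitude is the stable reading of
"divide by the mean permutation enrichment score" (the literal signed mean
remains available via the null vector returned by `permutation_null`).
p = (1 + #{|ES_perm| ≥ |ES_obs|}) / (n_perm + 1): two-sided, add-one, so
p ≥ 1/(n_perm+1) and BH over objects is well-defined. All-zero nulls are
degenerate and rejected.

Defaults: n_perm = 1000 for group-level MRA/GSEA, seedable everywhere.

## Per-cell activity and cell cycle

A cell's signature is (x_gc − mean_g)/sd_g on log₁₀ TPM with population
(÷n) standard deviation, floored at 10⁻⁸; constant genes are dropped. The
z-scale keeps highly expressed genes from dominating the weighted-mean ES.
Per object, n_perm = 100 shared gene-label permutations are evaluated
against *every* cell and pooled into one null (size n_perm × n_cells);
each cell's NES is its observed ES over the sign-matched mean |ES| of that
pool. The shared pool is what makes activities comparable across cells,
and it gives exact antisymmetry: negating all signatures negates the
activity matrix. 100 permutations (not 1000) per object keeps the cost
linear in cells while the pooling supplies an ample null.

Cell-cycle module scores: genes are cut into 24 equal-size bins by
dataset-wide mean LogNormalized expression; for each phase-list gene, 100
control genes are drawn from its bin (without replacement when the bin
allows, excluding list genes), and the score is mean(list) −
mean-of-per-gene-control-means. Averaging control means *per list gene* —
rather than pooling all controls into one deduplicated set — keeps bins
with several list genes proportionally represented; with a pooled control
set, a list concentrated in high-expression bins is compared against a
flat bin average and acquires a systematic positive offset (observed as
≈ +0.05 on synthetic data, enough to erode the G1 call). Phase call: G1
iff both scores < 0, else argmax(s, g2m); at an exact score tie S wins
(arbitrary but fixed).

## Pseudobulk and bulk matching

Pseudobulk sums TPM over cells and rescales to 10⁶ — invariant to cell
duplication and to per-cell depth. Matching computes Spearman ρ on
log₁₀(TPM + 10⁻⁴) over the gene intersection (≥ 100 shared genes
required); Spearman makes the log transform inconsequential, which is
precisely why no choice of correlation scale needs defending. The full
intersection is used rather than detected-only genes. Rank ties in ρ are
broken by sample label.

## The synthetic-data generator

The generator emulates the structure the analyses assume, with known truth:

- **Architecture** (per seed): disjoint 50-target blocks for each of 20
  TFs, modes ±1, likelihoods uniform on (0,1]; 40-gene S and G2/M programs
  (+1.0 natural-log shift in their phase); a 30-gene high-variance group;
  gene lengths uniform on [300, 30000] bp; baseline log-means N(0, 1.25²).
- **Populations**: two populations of 300 cells (BE2C-like and
  Kelly-like at desk scale; the full-scale 962/1105 remains a config
  choice). TF activities are natural-log shifts applied to targets scaled
  by mode·likelihood; by default the first 5 TFs are at +2.0 in the first
  population — the recovery condition the validation is built on.
- **Cell cycle**: phases drawn per cell, Kelly-like predominantly S
  (fractions .1973/.5747/.2280 for G1/S/G2M) and BE2C-like spread more
  evenly (.2869/.3700/.3431).
- **High-variance group**: confined to the Kelly-like population, each
  cell independently "on" with probability 0.35 at +2.5 log — a bimodal,
  partially detected, high-mean/high-variance group of the
  metallothionein kind.
- **Counts**: expected proportions are the per-cell softmax of the logits;
  library sizes lognormal with σ = 0.35 around 38,000 reads/cell
  (reproducing a long right tail qualitatively); counts are negative
  binomial with size (dispersion) 2.0; each measurement then survives with
  probability μ/(μ + m), a logistic function of log μ with midpoint
  m = 0.5 expected counts — dropout concentrated on weakly expressed
  genes.
- **Bulk**: dropout-free expected profiles per population (phase mixture
  included, hv group at its expectation), TPM-scaled, with per-gene
  lognormal replicate noise (σ = 0.05).

Seeding: the architecture, the count draw and the bulk draw use three
separate streams derived from the one config seed, so simulating bulk does
not perturb the counts.

What the generator does **not** model: doublets, batch/ambient effects,
UMI duplication structure, spliced/unspliced counts, gene–gene correlation
beyond the regulon/program structure, and any particular biology of the
real cell lines — the between-population effect sizes are free parameters,
not estimates. Passing recovery tests therefore demonstrates correctness
of the algorithms under a faithful noise model, not performance guarantees
on any real dataset.

## Problem sizes and numerical choices

The validation suite runs at 2000 genes × 600 cells, the scale at which
every recovery property is already stable (MRA NES of planted TFs ≈ 20–30
versus |NES| < 1.5 for inactive ones); full-transcriptome sizes are a
configuration choice. Wilcoxon p-values switch from exact to asymptotic at
group size 25; NES denominators, p floors (10⁻³⁰⁰), sd floors (10⁻⁸) and
the min-size 10 eligibility rule are as given above. Degenerate inputs
(all-zero cells, all-zero permutation nulls, single-cell signatures,
empty panels) raise typed errors rather than propagating NaN; n_replicates
= 0 in the bulk simulator is valid and returns an empty panel.

## Known limitations

- `sample_shuffle` re-derives the full Wilcoxon signature per permutation;
  it is O(n_perm · DE) and meant for modest n_perm, while gene_shuffle is
  the fast default.
- The loess smoother has no robustness iterations; extreme variance
  outliers (which are exactly what the residual ranking is meant to find)
  slightly inflate the trend near their mean.
- Per-cell GSEA on gene sets ranks every cell separately and is an order
  of magnitude slower than the regulon path; regulons are the intended
  per-cell workload.
- BH-corrected permutation p-values are monotone in |NES| but not linearly
  related to it; no linear relationship is asserted or used.
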