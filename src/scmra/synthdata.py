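"""Ground-truth scRNA-seq simulator for two (or more) cell populations.

The generator emulates the statistical structure the downstream analyses
assume: two unsynchronized cell populations whose transcriptional
differences are driven by a handful of active TF regulons, cell-cycle S and
G2/M expression programs, a high-variance gene group confined to one
population (metallothionein-like: high mean, bimodal detection), lognormal
library-size variation around ~38,000 reads per cell, negative-binomial
counts with logistic dropout, and matched dropout-free bulk profiles.

Everything is deterministic given the config seed: the gene architecture,
the counts and the bulk panel each draw from their own seed-derived stream,
so e.g. ``simulate_bulk`` does not perturb ``simulate_counts``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import Regulon, TPM_TOTAL, ValidationError

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_truth",
    "simulate_counts",
    "simulate_bulk",
    "expected_profiles",
    "write_dataset",
]

PHASES = ("G1", "S", "G2M")

#: Log-scale (natural) shift applied to a phase program's genes in its phase.
PHASE_SHIFT = 1.0
#: Genes per phase program.
N_PHASE_GENES = 40
#: Per-cell probability that a high-variance gene is "on" in the hv population.
HV_ON_PROB = 0.35
#: Log shift of an "on" high-variance gene.
HV_LOG_SHIFT = 2.5
#: sd of the per-gene multiplicative replicate noise in bulk profiles.
BULK_REP_SIGMA = 0.05
#: sd of the baseline log-mean distribution across genes.
BASE_LOG_SD = 1.25

# Cell-cycle phase fractions (G1, S, G2M) per population. The Kelly-like
# population sits predominantly in S phase; the BE2C-like one is spread more
# evenly across phases.
DEFAULT_CYCLE_FRACTIONS = (
    (0.2869, 0.3700, 0.3431),  # BE2C-like
    (0.1973, 0.5747, 0.2280),  # Kelly-like
)


def _default_activity(n_tfs: int, n_pops: int) -> np.ndarray:
    """First 5 TFs active (+2 natural-log effect) in population 0."""
    act = np.zeros((n_tfs, n_pops))
    act[: min(5, n_tfs), 0] = 2.0
    return act


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the package's study conditions.

    ``activity_matrix`` holds natural-log expression shifts applied to each
    TF's targets (scaled by target mode and likelihood) per population.
    ``dispersion`` is the negative-binomial size parameter (variance =
    mu + mu^2/size); ``dropout_midpoint`` is the expected count at which a
    measurement survives with probability 1/2; ``library_sigma`` the sd of
    the lognormal library-size distribution.
    """

    n_genes: int = 2000
    n_tfs: int = 20
    targets_per_tf: int = 50
    populations: Tuple[Tuple[str, int], ...] = (("BE2C", 300), ("Kelly", 300))
    activity_matrix: Optional[np.ndarray] = None
    cycle_fraction: Optional[np.ndarray] = None
    hv_group_size: int = 30
    mean_reads_per_cell: float = 38000.0
    dispersion: float = 2.0
    dropout_midpoint: float = 0.5
    library_sigma: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        n_pops = len(self.populations)
        if self.activity_matrix is None:
            self.activity_matrix = _default_activity(self.n_tfs, n_pops)
        self.activity_matrix = np.asarray(self.activity_matrix, float)
        if self.cycle_fraction is None:
            if n_pops == 2:
                self.cycle_fraction = np.asarray(DEFAULT_CYCLE_FRACTIONS)
            else:
                self.cycle_fraction = np.full((n_pops, 3), 1.0 / 3.0)
        self.cycle_fraction = np.asarray(self.cycle_fraction, float)
        self.validate()

    def validate(self) -> None:
        for name, val in [
            ("n_genes", self.n_genes),
            ("n_tfs", self.n_tfs),
            ("targets_per_tf", self.targets_per_tf),
        ]:
            if val <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.hv_group_size < 0:
            raise ValidationError("hv_group_size must be >= 0")
        if any(n <= 0 for _, n in self.populations):
            raise ValidationError("population sizes must be > 0")
        if self.mean_reads_per_cell <= 0 or self.dispersion <= 0:
            raise ValidationError("mean_reads_per_cell and dispersion must be > 0")
        if self.library_sigma < 0:
            raise ValidationError("library_sigma must be >= 0")
        n_pops = len(self.populations)
        if self.activity_matrix.shape != (self.n_tfs, n_pops):
            raise ValidationError(
                f"activity_matrix must be {self.n_tfs} x {n_pops}, "
                f"got {self.activity_matrix.shape}"
            )
        if not np.all(np.isfinite(self.activity_matrix)):
            raise ValidationError("activity_matrix must be finite")
        if self.cycle_fraction.shape != (n_pops, 3):
            raise ValidationError(f"cycle_fraction must be {n_pops} x 3")
        if not np.allclose(self.cycle_fraction.sum(axis=1), 1.0):
            raise ValidationError("cycle_fraction rows must sum to 1")
        if (self.cycle_fraction < 0).any():
            raise ValidationError("cycle_fraction entries must be >= 0")
        reserved = (
            self.n_tfs * self.targets_per_tf + 2 * N_PHASE_GENES + self.hv_group_size
        )
        if self.n_tfs * self.targets_per_tf > self.n_genes:
            raise ValidationError(
                f"n_tfs * targets_per_tf = {self.n_tfs * self.targets_per_tf} exceeds "
                f"n_genes = {self.n_genes}"
            )
        if reserved > self.n_genes:
            raise ValidationError(
                f"need {reserved} genes for TF targets, phase programs and the "
                f"high-variance group, but n_genes = {self.n_genes}"
            )


@dataclass
class GroundTruth:
    """Everything needed to simulate and to verify recovery afterwards."""

    config: SimConfig
    gene_names: pd.Index
    gene_lengths: pd.Series  # bp
    base_log_mean: np.ndarray
    regulons: List[Regulon]
    activity_matrix: np.ndarray  # TF x population
    cell_labels: pd.Series  # population per barcode
    cycle_labels: pd.Series  # phase per barcode
    s_genes: List[str]
    g2m_genes: List[str]
    hv_genes: List[str] = field(default_factory=list)
    hv_population: Optional[str] = None

    @property
    def populations(self) -> List[str]:
        return [name for name, _ in self.config.populations]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def make_truth(config: SimConfig) -> GroundTruth:
    """Draw the gene architecture: regulons, programs, lengths, baselines.

    Deterministic given ``config.seed``. TF target blocks are disjoint;
    phase-program and high-variance genes come from the remaining pool, so
    regulon recovery is not confounded by cycle structure.
    """
    rng = _rng(config.seed, 0)
    n = config.n_genes
    genes = pd.Index([f"g{i:05d}" for i in range(n)], name="gene")
    lengths = pd.Series(rng.integers(300, 30001, size=n), index=genes, name="length_bp")
    base = rng.normal(0.0, BASE_LOG_SD, size=n)

    pool = rng.permutation(n)
    k = config.targets_per_tf
    regulons = []
    for t in range(config.n_tfs):
        idx = pool[t * k : (t + 1) * k]
        modes = rng.choice([1.0, -1.0], size=k)
        liks = 1.0 - rng.random(k)  # in (0, 1]
        regulons.append(
            Regulon(
                tf=f"TF{t + 1:02d}",
                targets=genes[idx].to_numpy(dtype=object),
                modes=modes,
                likelihoods=liks,
            )
        )
    used = config.n_tfs * k
    s_genes = list(genes[pool[used : used + N_PHASE_GENES]])
    used += N_PHASE_GENES
    g2m_genes = list(genes[pool[used : used + N_PHASE_GENES]])
    used += N_PHASE_GENES
    hv_genes = list(genes[pool[used : used + config.hv_group_size]])

    barcodes, pops, phases = [], [], []
    for p, (pop_name, n_cells) in enumerate(config.populations):
        ph = rng.choice(PHASES, size=n_cells, p=config.cycle_fraction[p])
        for i in range(n_cells):
            barcodes.append(f"{pop_name}_{i + 1:04d}")
            pops.append(pop_name)
            phases.append(ph[i])
    cell_index = pd.Index(barcodes, name="cell")

    return GroundTruth(
        config=config,
        gene_names=genes,
        gene_lengths=lengths,
        base_log_mean=base,
        regulons=regulons,
        activity_matrix=config.activity_matrix,
        cell_labels=pd.Series(pops, index=cell_index, name="population"),
        cycle_labels=pd.Series(phases, index=cell_index, name="phase"),
        s_genes=s_genes,
        g2m_genes=g2m_genes,
        hv_genes=hv_genes,
        hv_population=config.populations[-1][0] if config.hv_group_size else None,
    )


def _base_logits(truth: GroundTruth) -> np.ndarray:
    """Per (population, phase) natural-log expression logits, genes x pop x 3.

    Excludes the stochastic per-cell high-variance on/off states.
    """
    cfg = truth.config
    n = cfg.n_genes
    gene_loc = {g: i for i, g in enumerate(truth.gene_names)}
    n_pops = len(cfg.populations)
    logits = np.tile(truth.base_log_mean[:, None, None], (1, n_pops, 3))
    for t, reg in enumerate(truth.regulons):
        idx = np.array([gene_loc[g] for g in reg.targets])
        effect = reg.modes * reg.likelihoods  # per-target response
        for p in range(n_pops):
            logits[idx, p, :] += (truth.activity_matrix[t, p] * effect)[:, None]
    s_idx = np.array([gene_loc[g] for g in truth.s_genes], dtype=np.intp)
    g2m_idx = np.array([gene_loc[g] for g in truth.g2m_genes], dtype=np.intp)
    logits[s_idx, :, PHASES.index("S")] += PHASE_SHIFT
    logits[g2m_idx, :, PHASES.index("G2M")] += PHASE_SHIFT
    return logits


def expected_profiles(truth: GroundTruth) -> pd.DataFrame:
    """Expected relative expression (read proportions) per population.

    Mixes phase-specific softmax profiles by the population's cycle
    fractions and applies the expectation of the high-variance on/off state;
    columns sum to 1. Useful for checking effect monotonicity before any
    sampling noise.
    """
    cfg = truth.config
    logits = _base_logits(truth)
    gene_loc = {g: i for i, g in enumerate(truth.gene_names)}
    cols = {}
    for p, (pop_name, _) in enumerate(cfg.populations):
        rel = np.exp(logits[:, p, :])  # genes x 3 phases
        if truth.hv_genes and pop_name == truth.hv_population:
            hv_idx = np.array([gene_loc[g] for g in truth.hv_genes], dtype=np.intp)
            rel[hv_idx, :] *= (1 - HV_ON_PROB) + HV_ON_PROB * np.exp(HV_LOG_SHIFT)
        prof = (rel / rel.sum(axis=0, keepdims=True)) @ cfg.cycle_fraction[p]
        cols[pop_name] = prof / prof.sum()
    return pd.DataFrame(cols, index=truth.gene_names)


def simulate_counts(
    truth: GroundTruth, config: Optional[SimConfig] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the genes x cells count matrix and the per-cell annotation.

    Per cell: library size L ~ lognormal(mean = mean_reads_per_cell,
    sd = library_sigma on the log scale); expected counts mu = L * softmax
    of the cell's logits (baseline + TF activity + phase program + any
    high-variance on-state); counts ~ NB(size = dispersion, mean = mu);
    finally each measurement survives dropout with probability
    mu / (mu + dropout_midpoint), a logistic function of log mu centred at
    the midpoint. The annotation records population, phase and the realized
    total reads per cell.
    """
    cfg = config if config is not None else truth.config
    if cfg.n_genes != len(truth.gene_names):
        raise ValidationError("config inconsistent with truth (n_genes differs)")
    rng = _rng(cfg.seed, 1)
    logits = _base_logits(truth)
    gene_loc = {g: i for i, g in enumerate(truth.gene_names)}
    pop_index = {name: p for p, (name, _) in enumerate(cfg.populations)}
    phase_index = {ph: j for j, ph in enumerate(PHASES)}

    n_cells = len(truth.cell_labels)
    n_genes = cfg.n_genes
    pops = truth.cell_labels.to_numpy()
    phases = truth.cycle_labels.to_numpy()
    cell_logits = np.empty((n_genes, n_cells))
    for c in range(n_cells):
        cell_logits[:, c] = logits[:, pop_index[pops[c]], phase_index[phases[c]]]
    if truth.hv_genes and truth.hv_population is not None:
        hv_idx = np.array([gene_loc[g] for g in truth.hv_genes], dtype=np.intp)
        hv_cells = np.flatnonzero(pops == truth.hv_population)
        on = rng.random((len(hv_idx), len(hv_cells))) < HV_ON_PROB
        cell_logits[np.ix_(hv_idx, hv_cells)] += HV_LOG_SHIFT * on

    # softmax per cell -> expected read proportions
    cell_logits -= cell_logits.max(axis=0, keepdims=True)
    prop = np.exp(cell_logits)
    prop /= prop.sum(axis=0, keepdims=True)

    if cfg.library_sigma > 0:
        mu_log = np.log(cfg.mean_reads_per_cell) - cfg.library_sigma**2 / 2.0
        lib = rng.lognormal(mu_log, cfg.library_sigma, size=n_cells)
    else:
        lib = np.full(n_cells, cfg.mean_reads_per_cell)

    mu = prop * lib[None, :]
    size = cfg.dispersion
    counts = rng.negative_binomial(size, size / (size + mu)).astype(np.int64)
    if cfg.dropout_midpoint > 0:
        keep_p = mu / (mu + cfg.dropout_midpoint)
        counts = counts * (rng.random(mu.shape) < keep_p)

    counts_df = pd.DataFrame(counts, index=truth.gene_names, columns=truth.cell_labels.index)
    annotation = pd.DataFrame(
        {
            "population": truth.cell_labels,
            "phase": truth.cycle_labels,
            "n_reads": counts.sum(axis=0),
        }
    )
    return counts_df, annotation


def simulate_bulk(
    truth: GroundTruth, n_replicates: int, seed: Optional[int] = None
) -> pd.DataFrame:
    """Matched bulk TPM profiles, one column per population per replicate.

    Bulk profiles are the dropout-free expected expression of each
    population (phase mixture included, high-variance genes at their
    expectation), TPM-scaled after dividing by gene length, with mild
    per-gene lognormal replicate noise (sd 0.05). ``n_replicates=0`` gives
    an empty panel.
    """
    if n_replicates < 0:
        raise ValidationError("n_replicates must be >= 0")
    rng = _rng(truth.config.seed if seed is None else seed, 2)
    profiles = expected_profiles(truth)
    len_kb = truth.gene_lengths.to_numpy(float) / 1e3
    cols = {}
    for pop in profiles.columns:
        base = profiles[pop].to_numpy()
        for r in range(n_replicates):
            noisy = base * np.exp(rng.normal(0.0, BULK_REP_SIGMA, size=len(base)))
            rate = noisy / len_kb
            cols[f"{pop}_bulk{r + 1}"] = rate / rate.sum() * TPM_TOTAL
    return pd.DataFrame(cols, index=truth.gene_names)


def write_dataset(outdir: str, truth: GroundTruth, counts, annotation, bulk=None) -> None:
    """Write the simulated dataset as plain-text files (10x triplet + TSV/CSV/GMT/JSON)."""
    import json
    import os

    from . import io_formats

    os.makedirs(outdir, exist_ok=True)
    gene_table = pd.DataFrame(
        {
            "gene_id": truth.gene_names,
            "symbol": truth.gene_names,
            "length_bp": truth.gene_lengths,
        },
        index=truth.gene_names,
    )
    io_formats.write_mtx_triplet(outdir, counts, gene_table)
    annotation.to_csv(os.path.join(outdir, "annotation.csv"))
    io_formats.write_regulons(os.path.join(outdir, "regulons.tsv"), truth.regulons)
    sets = {f"{r.tf}_targets": list(r.targets) for r in truth.regulons}
    sets["S_program"] = truth.s_genes
    sets["G2M_program"] = truth.g2m_genes
    io_formats.write_gmt(os.path.join(outdir, "sets.gmt"), sets)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(
            {
                "seed": truth.config.seed,
                "populations": {name: n for name, n in truth.config.populations},
                "activity_matrix": truth.activity_matrix.tolist(),
                "tfs": [r.tf for r in truth.regulons],
                "s_genes": truth.s_genes,
                "g2m_genes": truth.g2m_genes,
                "hv_genes": truth.hv_genes,
                "hv_population": truth.hv_population,
            },
            fh,
            indent=1,
        )
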