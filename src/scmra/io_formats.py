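"""Readers and writers for every on-disk format the pipeline touches.

Formats: 10x-style Matrix Market triplet directories (matrix.mtx,
features.tsv, barcodes.tsv), dense genes x cells CSV, GMT gene-set
collections, 4-column regulon TSV, and gene annotation tables. All readers
validate and raise :class:`~scmra.containers.FormatError` on malformed input
rather than silently coercing; every format round-trips bit-faithfully.
Files with a ``.gz`` suffix are handled transparently.
"""

from __future__ import annotations

import gzip
import io
import os
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import FormatError, Regulon

__all__ = [
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_dense_csv",
    "write_dense_csv",
    "read_gmt",
    "write_gmt",
    "read_regulons",
    "write_regulons",
    "make_unique",
]


def _find(path_base: str) -> str:
    """Return path_base or path_base + '.gz', whichever exists."""
    for p in (path_base, path_base + ".gz"):
        if os.path.exists(p):
            return p
    raise FormatError(f"missing file: {path_base}[.gz]")


def _open_text(path: str, mode: str = "rt"):
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def make_unique(names: Sequence[str]) -> List[str]:
    """Deduplicate symbols by suffixing '.1', '.2', ... (Cell Ranger style)."""
    seen: Dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


# ---------------------------------------------------------------------------
# Matrix Market triplet directory (10x convention)
# ---------------------------------------------------------------------------

def read_mtx_triplet(dir_path: str):
    """Read a 10x-style triplet directory.

    Returns ``(counts, gene_table, barcodes)`` where *counts* is an integer
    genes x cells DataFrame indexed by (deduplicated) gene symbol, and
    *gene_table* is a DataFrame with columns ``gene_id``, ``symbol``,
    ``length_bp`` sharing that index.
    """
    mtx_path = _find(os.path.join(dir_path, "matrix.mtx"))
    feat_path = _find(os.path.join(dir_path, "features.tsv"))
    bc_path = _find(os.path.join(dir_path, "barcodes.tsv"))

    with _open_text(mtx_path, "rb") as fh:
        mat = scipy.io.mmread(fh)
    mat = scipy.sparse.coo_matrix(mat)
    dense = np.asarray(mat.todense())
    if not np.issubdtype(dense.dtype, np.integer):
        if not np.allclose(dense, np.round(dense)):
            raise FormatError(f"{mtx_path}: non-integer entries in count matrix")
        dense = np.round(dense).astype(np.int64)
    if dense.size and dense.min() < 0:
        raise FormatError(f"{mtx_path}: negative entries in count matrix")

    features = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    if features.shape[1] < 3:
        raise FormatError(f"{feat_path}: expected 3 columns (gene_id, symbol, length_bp)")
    if features.shape[0] != dense.shape[0]:
        raise FormatError(
            f"{feat_path}: {features.shape[0]} features but matrix has {dense.shape[0]} rows"
        )
    with _open_text(bc_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if len(barcodes) != dense.shape[1]:
        raise FormatError(
            f"{bc_path}: {len(barcodes)} barcodes but matrix has {dense.shape[1]} columns"
        )

    lengths = pd.to_numeric(features.iloc[:, 2], errors="coerce")
    if lengths.isna().any() or (lengths < 1).any():
        raise FormatError(f"{feat_path}: length_bp must be a positive integer")
    if not features.iloc[:, 0].is_unique:
        raise FormatError(f"{feat_path}: gene_id column contains duplicates")

    symbols = make_unique(list(features.iloc[:, 1]))
    gene_table = pd.DataFrame(
        {
            "gene_id": features.iloc[:, 0].to_numpy(),
            "symbol": features.iloc[:, 1].to_numpy(),
            "length_bp": lengths.astype(int).to_numpy(),
        },
        index=pd.Index(symbols, name="gene"),
    )
    counts = pd.DataFrame(dense, index=gene_table.index, columns=barcodes)
    return counts, gene_table, barcodes


def write_mtx_triplet(dir_path: str, counts: pd.DataFrame, gene_table: pd.DataFrame) -> None:
    """Write counts + annotation as a 10x-style triplet directory."""
    os.makedirs(dir_path, exist_ok=True)
    sp = scipy.sparse.coo_matrix(counts.to_numpy())
    # mmwrite writes integer fields for integer dtype
    scipy.io.mmwrite(os.path.join(dir_path, "matrix.mtx"), sp.astype(np.int64))
    gt = gene_table.loc[counts.index]
    gt[["gene_id", "symbol", "length_bp"]].to_csv(
        os.path.join(dir_path, "features.tsv"), sep="\t", header=False, index=False
    )
    with open(os.path.join(dir_path, "barcodes.tsv"), "w") as fh:
        for bc in counts.columns:
            fh.write(f"{bc}\n")


# ---------------------------------------------------------------------------
# Dense CSV (genes x cells, header = barcodes)
# ---------------------------------------------------------------------------

def read_dense_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    arr = df.to_numpy()
    if arr.size and not np.allclose(arr, np.round(arr)):
        raise FormatError(f"{path}: non-integer entries in count matrix")
    if arr.size and arr.min() < 0:
        raise FormatError(f"{path}: negative entries")
    out = df.round().astype(np.int64)
    out.index = pd.Index(make_unique(list(df.index.astype(str))), name="gene")
    return out


def write_dense_csv(path: str, counts: pd.DataFrame) -> None:
    counts.to_csv(path)


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path: str) -> Dict[str, List[str]]:
    """Parse a GMT file into an ordered {name: [genes]} mapping.

    Duplicate genes within a set are removed, keeping the first occurrence.
    """
    sets: Dict[str, List[str]] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = genes
    return sets


def write_gmt(path: str, sets: Dict[str, Sequence[str]], description: str = "na") -> None:
    with _open_text(path, "wt") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Regulon TSV (tf, target, mode, likelihood)
# ---------------------------------------------------------------------------

_REGULON_COLS = ["tf", "target", "mode", "likelihood"]


def read_regulons(path: str) -> List[Regulon]:
    """Read a 4-column TSV (with header) into a list of Regulons.

    Rows are grouped by TF preserving first-appearance order; modes must lie
    in [-1, 1] and likelihoods in (0, 1].
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _REGULON_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    pairs = df[["tf", "target"]].apply(tuple, axis=1)
    dup = pairs.duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2  # header is line 1
        raise FormatError(f"{path}: duplicate (tf, target) pair at line {row}")
    bad_mode = ~df["mode"].between(-1, 1) | df["mode"].isna()
    if bad_mode.any():
        row = int(np.flatnonzero(bad_mode.to_numpy())[0]) + 2
        raise FormatError(f"{path}: mode outside [-1, 1] at line {row}")
    bad_lik = ~((df["likelihood"] > 0) & (df["likelihood"] <= 1))
    if bad_lik.any():
        row = int(np.flatnonzero(bad_lik.to_numpy())[0]) + 2
        raise FormatError(f"{path}: likelihood outside (0, 1] at line {row}")
    self_edge = df["tf"] == df["target"]
    if self_edge.any():
        row = int(np.flatnonzero(self_edge.to_numpy())[0]) + 2
        raise FormatError(f"{path}: self-edge at line {row}")

    regs = []
    for tf, grp in df.groupby("tf", sort=False):
        regs.append(
            Regulon(
                tf=str(tf),
                targets=grp["target"].astype(str).to_numpy(dtype=object),
                modes=grp["mode"].to_numpy(float),
                likelihoods=grp["likelihood"].to_numpy(float),
            )
        )
    return regs


def write_regulons(path: str, regulons: Sequence[Regulon]) -> None:
    rows = []
    for r in regulons:
        for t, m, l in zip(r.targets, r.modes, r.likelihoods):
            rows.append((r.tf, t, m, l))
    pd.DataFrame(rows, columns=_REGULON_COLS).to_csv(path, sep="\t", index=False)
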