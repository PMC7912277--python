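"""Shared in-memory containers.

Matrices are oriented genes x cells throughout the package (rows indexed by
gene symbol, columns by cell barcode); on-disk writers emit the 10x
orientation. Expression values travel inside :class:`ExprMatrix`, which tags
the pandas DataFrame with its unit so downstream operations can refuse input
on the wrong scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExprMatrix",
    "Regulon",
    "EnrichmentResult",
    "FormatError",
    "ValidationError",
]

#: Expression units understood by the pipeline.
UNITS = ("TPM", "log10TPM", "lognorm")

TPM_TOTAL = 1e6


class FormatError(ValueError):
    """Malformed on-disk input; readers raise this instead of coercing."""


class ValidationError(ValueError):
    """In-memory object violates a container invariant."""


@dataclass
class ExprMatrix:
    """A genes x cells expression matrix with a unit tag.

    Parameters
    ----------
    values
        DataFrame with gene symbols as index and cell barcodes as columns.
    unit
        One of ``"TPM"`` (columns sum to 1e6), ``"log10TPM"``
        (log10(TPM + pseudocount)) or ``"lognorm"``
        (ln(1 + count/colsum * scale), Seurat's LogNormalize scale).
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not self.values.index.is_unique:
            raise ValidationError("gene index contains duplicates")
        arr = self.values.to_numpy()
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        if self.unit == "TPM" and arr.size:
            colsum = arr.sum(axis=0)
            if not np.allclose(colsum, TPM_TOTAL, rtol=1e-6):
                raise ValidationError("TPM columns must sum to 1e6")
        if self.unit == "lognorm" and arr.size and arr.min() < 0:
            raise ValidationError("lognorm values must be >= 0")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns

    def require_unit(self, unit: str) -> "ExprMatrix":
        if self.unit != unit:
            raise ValidationError(f"expected {unit} matrix, got {self.unit}")
        return self


@dataclass
class Regulon:
    """A transcription factor with its signed, weighted target list.

    ``mode`` is the sign/strength of regulation in [-1, 1]; ``likelihood`` is
    a confidence weight in (0, 1]. The TF itself never appears among its own
    targets.
    """

    tf: str
    targets: np.ndarray  # gene symbols, dtype=object/str
    modes: np.ndarray  # float in [-1, 1]
    likelihoods: np.ndarray  # float in (0, 1]

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=object)
        self.modes = np.asarray(self.modes, dtype=float)
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        n = len(self.targets)
        if len(self.modes) != n or len(self.likelihoods) != n:
            raise ValidationError(f"regulon {self.tf}: target/mode/likelihood lengths differ")
        if len(set(self.targets)) != n:
            raise ValidationError(f"regulon {self.tf}: duplicate targets")
        if self.tf in set(self.targets):
            raise ValidationError(f"regulon {self.tf}: self-edge")
        if n and (np.abs(self.modes).max() > 1 or not np.all(np.isfinite(self.modes))):
            raise ValidationError(f"regulon {self.tf}: mode outside [-1, 1]")
        if n and (self.likelihoods.min() <= 0 or self.likelihoods.max() > 1):
            raise ValidationError(f"regulon {self.tf}: likelihood outside (0, 1]")

    def __len__(self) -> int:
        return len(self.targets)

    def restrict(self, universe) -> "Regulon":
        """Return the sub-regulon whose targets lie in *universe*."""
        uni = set(universe)
        keep = np.array([t in uni for t in self.targets], dtype=bool)
        return Regulon(self.tf, self.targets[keep], self.modes[keep], self.likelihoods[keep])


@dataclass
class EnrichmentResult:
    """Enrichment of one gene set / regulon against one signature."""

    name: str
    es: float
    nes: float
    p_value: float
    fdr: float = field(default=float("nan"))
    n_perm: int = 0

    @property
    def direction(self) -> int:
        return 1 if self.nes >= 0 else -1
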