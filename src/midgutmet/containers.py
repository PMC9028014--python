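"""Core in-memory containers shared across the pipeline.

The pipeline's entry object is a raw gene x cell integer count matrix
(:class:`CountMatrix`); every normalization / transformation step produces an
:class:`ExpressionMatrix` that carries provenance flags (which size-factor
method was applied, whether values are on TPM or log2-TPM scale, which entries
were imputed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MidgutError(ValueError):
    """Base error for invalid inputs or configurations."""


class ParseError(MidgutError):
    """Malformed input file; message carries the offending line when known."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise MidgutError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Raw gene x cell non-negative integer counts with IDs and optional labels."""

    counts: np.ndarray  # (n_genes, n_cells) integer
    gene_ids: list
    cell_ids: list
    labels: list | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.counts.ndim != 2:
            raise MidgutError("counts must be a 2-D gene x cell matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise MidgutError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} gene ids / {len(self.cell_ids)} cell ids"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise MidgutError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise MidgutError("counts must be non-negative")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != len(self.cell_ids):
                raise MidgutError("labels must have one entry per cell")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise MidgutError(f"gene {gene_id!r} not present") from None


@dataclass
class ExpressionMatrix:
    """Real-valued expression matrix with provenance flags.

    ``scale`` is one of ``counts`` (possibly size-factor divided, hence real),
    ``tpm`` or ``log2tpm``.  ``imputed_mask`` is True exactly at entries whose
    value was changed by imputation.
    """

    values: np.ndarray  # (n_genes, n_cells) float
    gene_ids: list
    cell_ids: list
    scale: str = "counts"
    labels: list | None = None
    size_factor_method: str | None = None
    imputed_mask: np.ndarray | None = None
    pseudocount: float | None = None
    zero_cells: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise MidgutError("values shape inconsistent with id lists")
        if self.scale not in ("counts", "tpm", "log2tpm"):
            raise MidgutError(f"unknown scale {self.scale!r}")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise MidgutError(f"gene {gene_id!r} not present") from None

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            gene_ids=list(self.gene_ids),
            cell_ids=list(self.cell_ids),
            scale=self.scale,
            labels=None if self.labels is None else list(self.labels),
            size_factor_method=self.size_factor_method,
            imputed_mask=None if self.imputed_mask is None else self.imputed_mask.copy(),
            pseudocount=self.pseudocount,
            zero_cells=list(self.zero_cells),
        )
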