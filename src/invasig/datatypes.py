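"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MITO_PREFIX = "MT-"

#: columns every per-cell metadata table must carry
CELL_META_COLUMNS = (
    "sample",
    "condition",
    "n_umis",
    "n_genes_detected",
    "mito_frac",
    "doublet_score",
)


class SchemaError(ValueError):
    """Raised when a table is missing required columns or labels misalign."""


@dataclass
class CellMatrix:
    """Gene x cell UMI count matrix with per-cell metadata.

    ``counts`` has genes on rows and cells on columns.  ``cell_meta`` is
    indexed by barcode and carries the sample/condition labels plus the
    QC covariates (total UMIs, genes detected, mitochondrial fraction,
    doublet score).  ``n_umis`` and ``n_genes_detected`` are derived from
    the counts and kept consistent by the constructors here.
    """

    counts: np.ndarray
    gene_names: list[str]
    barcodes: list[str]
    cell_meta: pd.DataFrame

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        gene_names: Sequence[str],
        barcodes: Sequence[str],
        sample: Sequence[str] | str,
        condition: Sequence[str] | str,
        doublet_score: Sequence[float] | None = None,
    ) -> "CellMatrix":
        """Build a matrix and derive the per-cell QC covariates."""
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise SchemaError("counts must be a 2-D gene x cell matrix")
        if counts.shape != (len(gene_names), len(barcodes)):
            raise SchemaError(
                f"counts shape {counts.shape} does not match "
                f"{len(gene_names)} genes x {len(barcodes)} cells"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        gene_names = [str(g) for g in gene_names]
        barcodes = [str(b) for b in barcodes]
        n_cells = len(barcodes)
        if isinstance(sample, str):
            sample = [sample] * n_cells
        if isinstance(condition, str):
            condition = [condition] * n_cells
        if doublet_score is None:
            doublet_score = np.zeros(n_cells)
        mito = np.array([g.upper().startswith(MITO_PREFIX) for g in gene_names])
        n_umis = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(
                n_umis > 0, counts[mito].sum(axis=0) / np.maximum(n_umis, 1), 0.0
            )
        meta = pd.DataFrame(
            {
                "sample": list(sample),
                "condition": list(condition),
                "n_umis": n_umis.astype(int),
                "n_genes_detected": (counts > 0).sum(axis=0).astype(int),
                "mito_frac": mito_frac,
                "doublet_score": np.asarray(doublet_score, dtype=float),
            },
            index=pd.Index(barcodes, name="barcode"),
        )
        return cls(counts=counts, gene_names=gene_names, barcodes=barcodes, cell_meta=meta)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def validate(self) -> None:
        missing = [c for c in CELL_META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise SchemaError(f"cell_meta missing columns: {missing}")
        if list(self.cell_meta.index) != self.barcodes:
            raise SchemaError("cell_meta rows do not align 1:1 with barcodes")
        if self.counts.shape != (self.n_genes, self.n_cells):
            raise SchemaError("counts shape does not match labels")
        n_umis = self.counts.sum(axis=0)
        if not np.array_equal(n_umis, self.cell_meta["n_umis"].to_numpy()):
            raise SchemaError("n_umis metadata inconsistent with counts")
        detected = (self.counts > 0).sum(axis=0)
        if not np.array_equal(detected, self.cell_meta["n_genes_detected"].to_numpy()):
            raise SchemaError("n_genes_detected metadata inconsistent with counts")

    def subset_cells(self, keep: np.ndarray) -> "CellMatrix":
        """Subset to the cells selected by a boolean or integer index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CellMatrix(
            counts=self.counts[:, keep],
            gene_names=self.gene_names,
            barcodes=[self.barcodes[i] for i in keep],
            cell_meta=self.cell_meta.iloc[keep].copy(),
        )


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every simulated object.

    Only the fields relevant to the generator that produced it are set.
    """

    de_gene_names: list[str] | None = None
    qc_flags: dict[str, str] | None = None  # barcode -> {lowq, doublet, good}
    true_group: dict[str, str] | None = None  # patient -> {high, low}
    true_class: dict[int, str] | None = None  # cell id -> {strand, core, single}
    true_fiber_angle: float | None = None
    extras: dict = field(default_factory=dict)
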