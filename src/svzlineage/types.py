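"""Core in-memory containers shared across the pipeline.

The substrate of every expression operation is :class:`CountMatrix`: a
cells x genes raw integer count matrix with per-cell and per-gene metadata
tables, mirroring the CellRanger triplet layout on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


def _as_csr(x) -> sp.csr_matrix:
    if sp.issparse(x):
        return x.tocsr()
    return sp.csr_matrix(np.asarray(x))


@dataclass
class CountMatrix:
    """Raw integer counts (cells x genes) plus aligned metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per cell.
    cell_meta
        DataFrame indexed by cell barcode, one row per cell.
    gene_meta
        DataFrame indexed by gene name, one row per gene.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self):
        self.counts = _as_csr(self.counts)
        if self.counts.shape != (len(self.cell_meta), len(self.gene_meta)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match metadata "
                f"({len(self.cell_meta)} cells, {len(self.gene_meta)} genes)"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def gene_names(self) -> pd.Index:
        return self.gene_meta.index

    # ------------------------------------------------------------------
    def total_counts(self) -> np.ndarray:
        """UMI total per cell."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of genes with count > 0 per cell."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def fraction_counts(self, genes: Iterable[str]) -> np.ndarray:
        """Fraction of each cell's counts attributable to ``genes``."""
        mask = self.gene_names.isin(list(genes))
        if not mask.any():
            return np.zeros(self.n_cells)
        sub = np.asarray(self.counts[:, mask].sum(axis=1)).ravel()
        tot = self.total_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, sub / np.maximum(tot, 1), 0.0)
        return frac

    # ------------------------------------------------------------------
    def subset_cells(self, keep) -> "CountMatrix":
        """Subset by boolean mask, positional indices, or cell ids."""
        idx = self._resolve(keep, self.cell_ids)
        return CountMatrix(
            self.counts[idx], self.cell_meta.iloc[idx].copy(), self.gene_meta.copy()
        )

    def subset_genes(self, keep) -> "CountMatrix":
        idx = self._resolve(keep, self.gene_names)
        return CountMatrix(
            self.counts[:, idx], self.cell_meta.copy(), self.gene_meta.iloc[idx].copy()
        )

    @staticmethod
    def _resolve(keep, index: pd.Index) -> np.ndarray:
        keep = np.asarray(keep)
        if keep.dtype == bool:
            if keep.size != index.size:
                raise ValueError("boolean mask length mismatch")
            return np.flatnonzero(keep)
        if keep.dtype.kind in "iu":
            return keep
        pos = index.get_indexer(keep)
        if (pos < 0).any():
            missing = keep[pos < 0]
            raise KeyError(f"ids not found: {list(missing[:5])}")
        return pos

    # ------------------------------------------------------------------
    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_meta.copy(),
            var=self.gene_meta.copy(),
        )


@dataclass
class BarcodeMatrix:
    """Cells x sample-barcode counts used for demultiplexing."""

    counts: sp.csr_matrix
    cell_ids: pd.Index
    barcode_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = _as_csr(self.counts)
        self.cell_ids = pd.Index(self.cell_ids)
        if not len(self.barcode_names):
            self.barcode_names = [f"BC{i}" for i in range(self.counts.shape[1])]
        if self.counts.shape != (len(self.cell_ids), len(self.barcode_names)):
            raise ValueError("barcode counts shape does not match metadata")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("barcode counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())
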