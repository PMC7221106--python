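"""Core in-memory containers shared across pipeline stages.

Matrices are stored genes x cells throughout, matching the on-disk 10x
convention of genes as rows.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp


def _as_str_array(x) -> np.ndarray:
    return np.asarray(x, dtype=object)


@dataclass
class GeneMatrix:
    """A genes x cells matrix with row/column identifiers.

    ``X`` may be a scipy sparse matrix or a dense ndarray; shape is
    (n_genes, n_cells). Gene and cell identifiers are kept in file order.
    """

    X: "sp.spmatrix | np.ndarray"
    genes: np.ndarray
    cells: np.ndarray

    def __post_init__(self):
        self.genes = _as_str_array(self.genes)
        self.cells = _as_str_array(self.cells)
        if self.X.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self, names) -> np.ndarray:
        """Indices of ``names`` in gene order; raises KeyError if absent."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as e:
            raise KeyError(f"gene {e.args[0]!r} not present in matrix") from None

    def subset_genes(self, mask_or_idx) -> "GeneMatrix":
        idx = np.asarray(mask_or_idx)
        X = self.X[idx, :] if not sp.issparse(self.X) else self.X.tocsr()[idx, :]
        return type(self)(X, self.genes[idx], self.cells)

    def subset_cells(self, mask_or_idx) -> "GeneMatrix":
        idx = np.asarray(mask_or_idx)
        X = self.X[:, idx] if not sp.issparse(self.X) else self.X.tocsc()[:, idx].tocsr()
        return type(self)(X, self.genes, self.cells[idx])

    def dense(self) -> np.ndarray:
        return self.X.toarray() if sp.issparse(self.X) else np.asarray(self.X)


class CountMatrix(GeneMatrix):
    """Sparse nonnegative integer UMI counts, genes x cells."""

    def __post_init__(self):
        super().__post_init__()
        if sp.issparse(self.X):
            if self.X.nnz and self.X.data.min() < 0:
                raise ValueError("counts must be nonnegative")
        elif np.asarray(self.X).size and np.asarray(self.X).min() < 0:
            raise ValueError("counts must be nonnegative")

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=0)).ravel()

    def detected_genes_per_cell(self) -> np.ndarray:
        if sp.issparse(self.X):
            return np.asarray((self.X > 0).sum(axis=0)).ravel()
        return (np.asarray(self.X) > 0).sum(axis=0)

    def cells_per_gene(self) -> np.ndarray:
        if sp.issparse(self.X):
            return np.asarray((self.X > 0).sum(axis=1)).ravel()
        return (np.asarray(self.X) > 0).sum(axis=1)


class ExpressionMatrix(GeneMatrix):
    """Log-normalized expression, genes x cells (nonnegative reals)."""


@dataclass
class LabeledDataset:
    """Synthetic counts plus the planted ground truth used by recovery tests."""

    counts: CountMatrix
    cell_type: np.ndarray  # label per cell
    true_markers: dict = field(default_factory=dict)  # gene -> type
    true_exclusive: dict = field(default_factory=dict)  # gene -> type (off elsewhere)
    true_pseudotime: Optional[np.ndarray] = None  # per cell, in [0, 1]
    true_module: dict = field(default_factory=dict)  # gene -> module id
    true_regulons: dict = field(default_factory=dict)  # tf -> {"targets": [...], "active_type": label}
    true_pathway_shift: dict = field(default_factory=dict)  # pathway -> (n_up, n_down, direction)
    qc_violations: dict = field(default_factory=dict)  # cell -> [rule, ...]

    def __post_init__(self):
        self.cell_type = _as_str_array(self.cell_type)
        if len(self.cell_type) != self.counts.n_cells:
            raise ValueError("cell_type length must match number of cells")
        if self.true_pseudotime is not None:
            pt = np.asarray(self.true_pseudotime, dtype=float)
            if pt.min() < 0 or pt.max() > 1:
                raise ValueError("true_pseudotime must lie in [0, 1]")
            self.true_pseudotime = pt
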