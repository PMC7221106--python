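"""Quality control, depth normalization, covariate regression and scaling.

The cell QC cascade excludes a cell when any bound is violated: fewer
than 200 detected genes, fewer than 1500 total UMI, more than 3000
detected genes, more than 15,000 UMI, or a mitochondrial or stress-gene
UMI share above 5%. Genes detected in fewer than 10 cells are dropped.
Mito/stress shares are measured as UMI fractions.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import QCThresholds
from .containers import CountMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

RULE_LOW_GENES = "low_genes"
RULE_LOW_UMI = "low_umi"
RULE_HIGH_GENES = "high_genes"
RULE_HIGH_UMI = "high_umi"
RULE_HIGH_MITO = "high_mito"
RULE_HIGH_STRESS = "high_stress"


@dataclass
class QCReport:
    """Per-cell QC metrics and the rules each excluded cell violated."""

    table: pd.DataFrame  # index: cell; columns: detected_genes, total_umi,
    #                      mito_frac, stress_frac, retained, violations
    n_before: int
    n_after: int

    def retained_cells(self) -> np.ndarray:
        return self.table.index.values[self.table["retained"].values]

    def retained_mask(self) -> np.ndarray:
        return self.table["retained"].values.copy()


def filter_genes(counts: CountMatrix, min_cells: int = 10) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be nonnegative")
    keep = counts.cells_per_gene() >= min_cells
    return counts.subset_genes(np.flatnonzero(keep))


def _share(counts: CountMatrix, gene_list: Sequence[str], totals: np.ndarray) -> np.ndarray:
    present = [g for g in gene_list if g in set(counts.genes)]
    if not present:
        return np.zeros(counts.n_cells)
    idx = counts.gene_index(present)
    sub = counts.X[idx, :] if not sp.issparse(counts.X) else counts.X.tocsr()[idx, :]
    s = np.asarray(sub.sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(totals > 0, s / totals, 0.0)


def default_gene_lists(genes: Sequence[str]) -> "tuple[list, list]":
    """Mito/stress genes found by the ``mt-`` / ``stress-`` name convention."""
    mito = [g for g in genes if str(g).lower().startswith("mt-")]
    stress = [g for g in genes if str(g).lower().startswith("stress-")]
    return mito, stress


def filter_cells(counts: CountMatrix, thresholds: Optional[QCThresholds] = None,
                 mito_genes: Optional[Sequence[str]] = None,
                 stress_genes: Optional[Sequence[str]] = None) -> QCReport:
    """Score every cell against the QC bounds; nothing is removed here.

    With ``thresholds.conjunctive_pairs`` the low (high) pair only
    excludes when both its gene and UMI bounds fail together.
    """
    th = thresholds or QCThresholds()
    th.validate()
    if mito_genes is None or stress_genes is None:
        conv_mito, conv_stress = default_gene_lists(counts.genes)
        mito_genes = conv_mito if mito_genes is None else mito_genes
        stress_genes = conv_stress if stress_genes is None else stress_genes
    gene_set = set(counts.genes)
    for name, lst in (("mito", mito_genes), ("stress", stress_genes)):
        missing = [g for g in lst if g not in gene_set]
        if missing:
            raise KeyError(f"{name} gene(s) not in matrix: {missing[:5]}")

    totals = counts.cell_totals()
    detected = counts.detected_genes_per_cell()
    mito_frac = _share(counts, mito_genes, totals)
    stress_frac = _share(counts, stress_genes, totals)

    low_g = detected < th.min_genes
    low_u = totals < th.min_umi
    high_g = detected > th.max_genes
    high_u = totals > th.max_umi
    if th.conjunctive_pairs:
        low_g = low_u = low_g & low_u
        high_g = high_u = high_g & high_u
    rule_masks = [
        (RULE_LOW_GENES, low_g), (RULE_LOW_UMI, low_u),
        (RULE_HIGH_GENES, high_g), (RULE_HIGH_UMI, high_u),
        (RULE_HIGH_MITO, mito_frac > th.max_mito_frac),
        (RULE_HIGH_STRESS, stress_frac > th.max_stress_frac),
    ]
    violations: List[List[str]] = [[] for _ in range(counts.n_cells)]
    for rule, mask in rule_masks:
        for c in np.flatnonzero(mask):
            if rule not in violations[c]:
                violations[c].append(rule)
    retained = np.array([not v for v in violations], dtype=bool)
    table = pd.DataFrame({
        "detected_genes": detected, "total_umi": totals,
        "mito_frac": mito_frac, "stress_frac": stress_frac,
        "retained": retained, "violations": [";".join(v) for v in violations],
    }, index=pd.Index(counts.cells, name="cell"))
    return QCReport(table=table, n_before=counts.n_cells, n_after=int(retained.sum()))


def apply_cell_filter(counts: CountMatrix, report: QCReport) -> CountMatrix:
    return counts.subset_cells(np.flatnonzero(report.retained_mask()))


def normalize_log(counts: CountMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Depth-normalize to ``scale_factor`` counts per cell and log-transform:
    value = log(1 + scale_factor * count / cell_total)."""
    totals = counts.cell_totals()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell(s) with zero total counts: {counts.cells[zero[:5]]}")
    X = counts.X.tocsc().astype(float) if sp.issparse(counts.X) else counts.X.astype(float)
    if sp.issparse(X):
        X = X.multiply(scale_factor / totals[None, :]).tocsr()
        X.data = np.log1p(X.data)
    else:
        X = np.log1p(X * (scale_factor / totals[None, :]))
    return ExpressionMatrix(X, counts.genes.copy(), counts.cells.copy())


def regress_and_scale(expr: ExpressionMatrix, covariates: np.ndarray,
                      clip: float = 10.0) -> np.ndarray:
    """Per gene: residual of a least-squares fit on the cell covariates
    (total UMI, mito fraction, stress fraction, ...), then centered,
    scaled to unit variance and clipped to ``±clip``.

    Collinear covariate columns are dropped with a logged warning;
    genes with zero residual variance come back as all-zero rows.
    Returns a dense genes x cells array.
    """
    Y = expr.dense()
    n_cells = Y.shape[1]
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] == n_cells and C.shape[1] != n_cells:
        C = C.T
    if C.shape[1] != n_cells:
        raise ValueError("covariate rows must match cells")
    X = np.column_stack([np.ones(n_cells), C.T])  # cells x (1 + k)
    # drop collinear columns (keep earliest independent set)
    keep = [0]
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear covariate column {j - 1}")
            logger.warning("regress_and_scale: dropped collinear covariate column %d", j - 1)
    X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    resid -= resid.mean(axis=1, keepdims=True)
    sd = resid.std(axis=1)
    nz = sd > 1e-12
    out = np.zeros_like(resid)
    out[nz] = resid[nz] / sd[nz, None]
    np.clip(out, -clip, clip, out=out)
    return out


def standard_covariates(counts: CountMatrix,
                        mito_genes: Optional[Sequence[str]] = None,
                        stress_genes: Optional[Sequence[str]] = None) -> np.ndarray:
    """The published regression covariates: total UMI, mito share, stress share."""
    if mito_genes is None or stress_genes is None:
        conv_m, conv_s = default_gene_lists(counts.genes)
        mito_genes = conv_m if mito_genes is None else mito_genes
        stress_genes = conv_s if stress_genes is None else stress_genes
    totals = counts.cell_totals().astype(float)
    return np.vstack([totals,
                      _share(counts, mito_genes, totals),
                      _share(counts, stress_genes, totals)])
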