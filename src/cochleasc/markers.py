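"""Differential expression and marker screens.

One-vs-rest and pairwise marker detection use the two-sided Wilcoxon
rank-sum test on log-normalized expression, with the published gates
min.pct = 0.25 and |avg log fold change| >= 0.25 (natural log) applied
before testing, and Bonferroni adjustment over the genes actually
tested. Also here: the top-N marker tables, the exclusive-expression
screen, cluster-averaged z-score matrices for heat maps, and the
twofold cross-dataset concordance comparison.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .containers import ExpressionMatrix

MARKER_COLUMNS = ["gene", "cluster", "avg_logfc", "pct_in", "pct_out", "p_value", "adj_p"]


def _dense_rows(X, idx):
    sub = X[idx, :]
    return sub.toarray() if sp.issparse(sub) else np.asarray(sub)


def de_two_groups(expr: ExpressionMatrix, cells_a: Sequence, cells_b: Sequence,
                  min_pct: float = 0.25, logfc_threshold: float = 0.25,
                  log2: bool = False, cluster_label="A") -> pd.DataFrame:
    """Wilcoxon rank-sum DE of group A vs group B.

    avg_logfc is the difference of group means on the log-normalized
    scale (natural log by default); positive means higher in A. Genes
    are tested only if max(pct_in, pct_out) >= min_pct and
    |avg_logfc| >= logfc_threshold; adj_p is Bonferroni over tested genes.
    """
    idx_a = _cell_indices(expr, cells_a)
    idx_b = _cell_indices(expr, cells_b)
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("groups must be disjoint")
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ValueError("each group needs at least 3 cells")

    if sp.issparse(expr.X):
        Xc = expr.X.tocsc()
        A = Xc[:, idx_a].toarray()
        B = Xc[:, idx_b].toarray()
    else:
        X = np.asarray(expr.X)
        A, B = X[:, idx_a], X[:, idx_b]

    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    lfc = mean_a - mean_b
    if log2:
        lfc = lfc / np.log(2)
    pct_in = (A > 0).mean(axis=1)
    pct_out = (B > 0).mean(axis=1)
    thr = logfc_threshold / np.log(2) if log2 else logfc_threshold
    tested = (np.maximum(pct_in, pct_out) >= min_pct) & (np.abs(lfc) >= thr)
    t_idx = np.flatnonzero(tested)
    if t_idx.size == 0:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="divide by zero")
        res = stats.mannwhitneyu(A[t_idx], B[t_idx], axis=1, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    adj = np.minimum(1.0, p * t_idx.size)
    return pd.DataFrame({
        "gene": expr.genes[t_idx], "cluster": cluster_label,
        "avg_logfc": lfc[t_idx], "pct_in": pct_in[t_idx], "pct_out": pct_out[t_idx],
        "p_value": p, "adj_p": adj,
    }).reset_index(drop=True)


def _cell_indices(expr: ExpressionMatrix, cells) -> np.ndarray:
    cells = np.asarray(cells)
    if cells.dtype == bool:
        return np.flatnonzero(cells)
    if np.issubdtype(cells.dtype, np.integer):
        return cells.astype(int)
    lookup = {c: i for i, c in enumerate(expr.cells)}
    return np.array([lookup[c] for c in cells], dtype=int)


def find_all_markers(expr: ExpressionMatrix, labels: Sequence,
                     min_pct: float = 0.25, logfc_threshold: float = 0.25,
                     log2: bool = False, genes: Optional[Sequence[str]] = None,
                     only_positive: bool = False) -> pd.DataFrame:
    """Each cluster vs all remaining cells; records flagged by direction."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters")
    sub = expr
    if genes is not None:
        present = [g for g in genes if g in set(expr.genes)]
        sub = expr.subset_genes(expr.gene_index(present))
    frames = []
    for cl in ids:
        in_cl = labels == cl
        rec = de_two_groups(sub, in_cl, ~in_cl, min_pct=min_pct,
                            logfc_threshold=logfc_threshold, log2=log2,
                            cluster_label=cl)
        frames.append(rec)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=MARKER_COLUMNS)
    out["positive"] = out["avg_logfc"] > 0
    if only_positive:
        out = out[out["positive"]].reset_index(drop=True)
    return out


def top_markers(records: pd.DataFrame, n: int = 25) -> pd.DataFrame:
    """Per cluster, the top ``n`` positive records by avg_logfc (descending),
    ties broken by adj_p ascending, then gene name."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pos = records[records["avg_logfc"] > 0].copy()
    pos = pos.sort_values(["cluster", "avg_logfc", "adj_p", "gene"],
                          ascending=[True, False, True, True], kind="mergesort")
    return pos.groupby("cluster", sort=True).head(n).reset_index(drop=True)


def detection_fractions(expr: ExpressionMatrix, labels: Sequence) -> pd.DataFrame:
    """Fraction of cells with count > 0, per gene per cluster."""
    labels = np.asarray(labels)
    X = expr.X
    cols = {}
    for cl in np.unique(labels):
        idx = np.flatnonzero(labels == cl)
        sub = X[:, idx] if not sp.issparse(X) else X.tocsc()[:, idx]
        det = (sub > 0).mean(axis=1)
        cols[cl] = np.asarray(det).ravel()
    return pd.DataFrame(cols, index=expr.genes)


def exclusive_genes(expr: ExpressionMatrix, labels: Sequence, target_cluster,
                    f_on: float = 0.3, f_off: float = 0.1) -> List[str]:
    """Genes detected in >= ``f_on`` of the target cluster's cells and
    <= ``f_off`` in every other cluster."""
    labels = np.asarray(labels)
    if target_cluster not in set(labels.tolist()):
        raise KeyError(f"cluster {target_cluster!r} not present")
    frac = detection_fractions(expr, labels)
    others = [c for c in frac.columns if c != target_cluster]
    mask = frac[target_cluster] >= f_on
    for c in others:
        mask &= frac[c] <= f_off
    return list(frac.index[mask])


def celltype_zscore_matrix(expr: ExpressionMatrix, labels: Sequence,
                           genes: Sequence[str]) -> pd.DataFrame:
    """Per gene: z-score across all cells, then mean within each cluster.

    Zero-variance genes produce all-zero rows with a warning.
    """
    labels = np.asarray(labels)
    idx = expr.gene_index(genes)
    Y = _dense_rows(expr.X, idx)
    mu = Y.mean(axis=1, keepdims=True)
    sd = Y.std(axis=1, keepdims=True)
    flat = (sd.ravel() <= 1e-12)
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s); rows set to 0")
    sd[sd <= 1e-12] = 1.0
    Z = (Y - mu) / sd
    Z[flat, :] = 0.0
    cols = {}
    for cl in np.unique(labels):
        cols[cl] = Z[:, labels == cl].mean(axis=1)
    return pd.DataFrame(cols, index=np.asarray(genes, dtype=object))


@dataclass
class ConcordanceResult:
    n_eligible: int
    n_concordant: int
    n_not_detected: int
    fold_threshold: float

    @property
    def fraction(self) -> float:
        return self.n_concordant / self.n_eligible if self.n_eligible else float("nan")


def cross_dataset_concordance(records: pd.DataFrame,
                              ref_means_a: Dict[str, float],
                              ref_means_b: Dict[str, float],
                              fold_threshold: float = 2.0) -> ConcordanceResult:
    """Direction concordance of DE genes against a reference dataset.

    A DE gene is eligible when its reference fold change (pseudocount 1
    on both means) is at least ``fold_threshold`` in either direction;
    it is concordant when the reference direction matches the DE
    direction. Genes missing from the reference are counted separately.
    """
    if any(v < 0 for v in ref_means_a.values()) or any(v < 0 for v in ref_means_b.values()):
        raise ValueError("reference means must be nonnegative")
    n_eligible = n_concordant = n_missing = 0
    for _, row in records.iterrows():
        g = row["gene"]
        if g not in ref_means_a or g not in ref_means_b:
            n_missing += 1
            continue
        fold = (ref_means_a[g] + 1.0) / (ref_means_b[g] + 1.0)
        if max(fold, 1.0 / fold) < fold_threshold:
            continue
        n_eligible += 1
        if (fold > 1.0) == (row["avg_logfc"] > 0):
            n_concordant += 1
    return ConcordanceResult(n_eligible=n_eligible, n_concordant=n_concordant,
                             n_not_detected=n_missing, fold_threshold=fold_threshold)
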