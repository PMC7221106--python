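"""Pseudotime ordering, DE along pseudotime, and phase-module discovery.

Cells are ordered by building a minimum spanning tree over cluster
centroids in the embedding, projecting each cell onto its nearest tree
edge, and taking normalized arc length from the root cluster as
pseudotime. A single degree-3 centroid is permitted, yielding two
branches. Genes that vary along pseudotime are found by an F-test of a
cubic-spline fit (3 internal knots at pseudotime quantiles) against an
intercept-only model, with Benjamini-Hochberg control at FDR 0.1; the
significant genes' smoothed, z-scored trends on a 50-point grid are
partitioned into phase modules by k-means (k fixed, or chosen from
2..8 by mean silhouette).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.interpolate import BSpline
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

from .clustering import Embedding
from .containers import ExpressionMatrix

TREND_GRID_SIZE = 50


@dataclass
class Trajectory:
    pseudotime: np.ndarray        # per cell, in [0, 1]
    branch: np.ndarray            # branch label per cell
    root_cluster: object
    centroids: np.ndarray         # cluster centroids in embedding order
    edges: List[tuple]            # MST edges as (cluster_i, cluster_j)

    @property
    def n_branches(self) -> int:
        return len(set(self.branch.tolist()))


@dataclass
class PhaseModules:
    assignment: Dict[str, str]    # gene -> module id
    trends: pd.DataFrame          # genes x grid of smoothed z-scored trends
    k: int
    grid: np.ndarray


def order_cells(emb: Embedding, labels: Sequence, root_cluster) -> Trajectory:
    """MST-over-centroids pseudotime with at most one bifurcation."""
    labels = np.asarray(labels)
    ids = list(np.unique(labels))
    if root_cluster not in ids:
        raise KeyError(f"root cluster {root_cluster!r} not present")
    cents = np.vstack([emb.coords[labels == c].mean(axis=0) for c in ids])
    n = len(ids)
    if n == 1:
        # degenerate: rank cells along the first embedding axis
        t = emb.coords[:, 0]
        t = (t - t.min()) / max(t.max() - t.min(), 1e-12)
        return Trajectory(pseudotime=t, branch=np.array(["branch_1"] * emb.n_cells),
                          root_cluster=root_cluster, centroids=cents, edges=[])
    D = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=2)
    mst = minimum_spanning_tree(D)
    n_comp, _ = connected_components(mst, directed=False)
    if n_comp != 1:
        raise ValueError("embedding centroids form a disconnected tree")
    mst = mst.toarray()
    adj = [[] for _ in range(n)]
    edges = []
    for i in range(n):
        for j in range(n):
            if mst[i, j] > 0:
                adj[i].append(j)
                adj[j].append(i)
                edges.append((ids[i], ids[j]))
    deg = np.array([len(a) for a in adj])
    if (deg >= 3).sum() > 1 or deg.max() > 3:
        warnings.warn("centroid tree has more than one bifurcation; branches "
                      "split at the bifurcation nearest the root only")

    root = ids.index(root_cluster)
    # arc-length distance from root along the tree
    dist = np.full(n, np.inf)
    parent = np.full(n, -1)
    dist[root] = 0.0
    stack = [root]
    order = []
    while stack:
        u = stack.pop()
        order.append(u)
        for v in adj[u]:
            if np.isinf(dist[v]):
                dist[v] = dist[u] + D[u, v]
                parent[v] = u
                stack.append(v)

    # branch label per tree node: split at the bifurcation nearest the root
    bif_nodes = np.flatnonzero(deg >= 3)
    bif = int(bif_nodes[np.argmin(dist[bif_nodes])]) if bif_nodes.size else -1
    node_branch = np.zeros(n, dtype=int)
    if bif >= 0:
        children = [v for v in adj[bif] if v != parent[bif]]
        for b, child in enumerate(sorted(children)):
            stack = [child]
            while stack:
                u = stack.pop()
                node_branch[u] = min(b + 1, 2)
                stack.extend(v for v in adj[u] if parent[v] == u)

    # project each cell onto the tree edge set
    seg = []
    for u in range(n):
        p = parent[u]
        if p >= 0:
            seg.append((p, u))
    t_raw = np.empty(emb.n_cells)
    cell_branch = np.empty(emb.n_cells, dtype=int)
    P = emb.coords
    best = np.full(emb.n_cells, np.inf)
    for (u, v) in seg:
        a, b = cents[u], cents[v]
        ab = b - a
        L = np.linalg.norm(ab)
        s = np.clip((P - a) @ ab / max(L * L, 1e-12), 0.0, 1.0)
        proj = a + s[:, None] * ab
        d = np.linalg.norm(P - proj, axis=1)
        upd = d < best
        best[upd] = d[upd]
        t_raw[upd] = dist[u] + s[upd] * L
        cell_branch[upd] = node_branch[v]
    t = t_raw / max(t_raw.max(), 1e-12)

    # trunk (branch 0) cells merge into the first branch for a 2-branch tree
    if bif >= 0:
        cell_branch[cell_branch == 0] = 1
        branch = np.array([f"branch_{b}" for b in cell_branch], dtype=object)
    else:
        branch = np.array(["branch_1"] * emb.n_cells, dtype=object)
    return Trajectory(pseudotime=t, branch=branch, root_cluster=root_cluster,
                      centroids=cents, edges=edges)


def pick_root_cluster(expr: ExpressionMatrix, labels: Sequence,
                      progenitor_markers: Sequence[str]):
    """The cluster with the highest mean expression of a progenitor marker
    set (the Sox2-style early-gene anchor)."""
    labels = np.asarray(labels)
    present = [g for g in progenitor_markers if g in set(expr.genes)]
    if not present:
        raise KeyError("no progenitor marker present in matrix")
    idx = expr.gene_index(present)
    sub = expr.X[idx, :]
    sub = sub.toarray() if sp.issparse(sub) else np.asarray(sub)
    score = sub.mean(axis=0)
    ids = np.unique(labels)
    means = [score[labels == c].mean() for c in ids]
    return ids[int(np.argmax(means))]


def _spline_basis(t: np.ndarray, eval_at: Optional[np.ndarray] = None) -> np.ndarray:
    """Cubic B-spline design matrix with 3 internal knots at quantiles."""
    internal = np.quantile(t, [0.25, 0.5, 0.75])
    lo, hi = t.min(), t.max()
    knots = np.concatenate([[lo] * 4, internal, [hi] * 4])
    x = t if eval_at is None else eval_at
    x = np.clip(x, lo, hi)
    return BSpline.design_matrix(x, knots, 3).toarray()


def de_along_pseudotime(expr: ExpressionMatrix, trajectory: Trajectory,
                        fdr: float = 0.1) -> pd.DataFrame:
    """F-test of a cubic-spline fit of expression on pseudotime against an
    intercept-only model, per gene, with BH q-values.

    Returns a table of all genes with p, q and a ``significant`` flag
    (q <= fdr).
    """
    t = np.asarray(trajectory.pseudotime, dtype=float)
    if np.ptp(t) <= 0:
        raise ValueError("pseudotime is constant")
    if len(t) < 50:
        raise ValueError("need at least 50 cells for pseudotime DE")
    Y = expr.dense()  # genes x cells
    X = _spline_basis(t)
    p_full = np.linalg.matrix_rank(X)
    n = len(t)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    rss1 = ((Y.T - X @ beta) ** 2).sum(axis=0)
    rss0 = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df1 = p_full - 1
    df2 = n - p_full
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    F = np.where(rss1 <= 1e-12, 0.0, F)  # constant genes: no signal
    p = stats.f.sf(F, df1, df2)
    p = np.where(np.isnan(p), 1.0, p)
    _, q, *_ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"gene": expr.genes, "p_value": p, "q_value": q,
                         "significant": q <= fdr})


def smooth_trends(expr: ExpressionMatrix, trajectory: Trajectory,
                  genes: Sequence[str],
                  grid_size: int = TREND_GRID_SIZE) -> pd.DataFrame:
    """Spline-smoothed, z-scored expression trend per gene on a fixed
    pseudotime grid."""
    t = np.asarray(trajectory.pseudotime, dtype=float)
    grid = np.linspace(t.min(), t.max(), grid_size)
    X = _spline_basis(t)
    Xg = _spline_basis(t, eval_at=grid)
    idx = expr.gene_index(genes)
    Y = expr.X[idx, :]
    Y = Y.toarray() if sp.issparse(Y) else np.asarray(Y)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (Xg @ beta).T  # genes x grid
    mu = fitted.mean(axis=1, keepdims=True)
    sd = fitted.std(axis=1, keepdims=True)
    sd[sd <= 1e-12] = 1.0
    Z = (fitted - mu) / sd
    return pd.DataFrame(Z, index=np.asarray(genes, dtype=object), columns=grid)


def cluster_gene_trends(expr: ExpressionMatrix, trajectory: Trajectory,
                        sig_genes: Sequence[str], k: "int | str" = 4,
                        seed: int = 0) -> PhaseModules:
    """Partition significant genes' smoothed trends into phase modules.

    ``k='auto'`` chooses k in 2..8 by mean silhouette. Modules are
    renamed phase_1..phase_k by the pseudotime position of their mean
    trend's maximum, so labels follow temporal order.
    """
    sig_genes = list(sig_genes)
    trends = smooth_trends(expr, trajectory, sig_genes)
    Z = trends.values
    if k == "auto":
        best_k, best_s = None, -np.inf
        for kk in range(2, 9):
            if kk >= len(sig_genes):
                break
            lab = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit_predict(Z)
            s = silhouette_samples(Z, lab)
            # macro average over clusters: a small incoherent cluster cannot
            # buy its way in by raising the per-gene mean
            macro = float(np.mean([s[lab == c].mean() for c in range(kk)]))
            if macro > best_s:
                best_k, best_s = kk, macro
        if best_k is None:
            raise ValueError("too few significant genes for auto k selection")
        k = best_k
    k = int(k)
    if len(sig_genes) < k:
        raise ValueError(f"fewer genes ({len(sig_genes)}) than modules ({k})")
    lab = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(Z)
    # temporal ordering of module ids by argmax of the mean trend
    peaks = [trends.columns.values[np.argmax(Z[lab == m].mean(axis=0))] for m in range(k)]
    order = np.argsort(peaks, kind="stable")
    rename = {int(old): f"phase_{new + 1}" for new, old in enumerate(order)}
    assignment = {g: rename[int(l)] for g, l in zip(sig_genes, lab)}
    return PhaseModules(assignment=assignment, trends=trends, k=k,
                        grid=trends.columns.values.astype(float))
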