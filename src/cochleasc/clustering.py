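"""Dimensionality reduction, shared-nearest-neighbor modularity clustering
over a resolution grid, and out-of-bag (OOB) resolution selection.

The published procedure clusters at resolutions 0.2-2.4 in 0.2 steps,
scores each partition with the OOB misclassification rate of a bagged
tree ensemble predicting cluster labels from the embedding, and keeps
the resolution with "a low OOB error and high cluster number". That
phrase is formalized here as a tolerance band: among partitions whose
OOB error is within ``selection_tolerance`` (default 0.05) of the
minimum, pick the one with the most clusters, breaking ties toward the
lowest resolution.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    """Cells x components coordinates with per-component explained variance."""

    coords: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class ClusteringResult:
    labels: np.ndarray  # cluster id per cell, 0..k-1, relabeled by size
    resolution: float
    n_clusters: int
    oob_error: float


def reduce_dims(scaled: np.ndarray, n_components: int = 20) -> Embedding:
    """Top principal components of the scaled genes x cells matrix.

    Deterministic up to sign; the sign of each component is fixed so its
    largest-magnitude gene loading is positive. ``n_components`` beyond
    the matrix rank is truncated with a warning.
    """
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    Y = scaled.T  # cells x genes
    max_rank = min(Y.shape)
    if n_components > max_rank:
        warnings.warn(f"n_components {n_components} exceeds rank bound {max_rank}; truncating")
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(Y)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(coords.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
    return Embedding(coords=coords, explained_variance=pca.explained_variance_ratio_)


def snn_graph(coords: np.ndarray, k_neighbors: int = 20,
              prune: float = 1 / 15) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each cell is connected to cells sharing k-nearest-neighbor sets
    (self included); edges with Jaccard overlap below ``prune`` are cut.
    """
    n = coords.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be < number of cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(coords)
    A = nn.kneighbors_graph(coords, mode="connectivity").tolil()
    A.setdiag(1)
    A = A.tocsr()
    shared = (A @ A.T).tocoo()
    k = k_neighbors + 1
    jaccard = shared.data / (2 * k - shared.data)
    keep = jaccard >= prune
    W = sp.coo_matrix((jaccard[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))
    W = W.tocsr()
    W.setdiag(0)
    W.eliminate_zeros()
    return W


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels], dtype=int)


def cluster_at_resolution(emb: Embedding, resolution: float, k_neighbors: int = 20,
                          seed: int = 0) -> ClusteringResult:
    """Modularity community detection on the SNN graph at one resolution.

    Labels are relabeled by decreasing cluster size, so they are stable
    under permutation of cell order. ``oob_error`` is left NaN; use
    :func:`oob_error` or :func:`scan_resolutions` to score.
    """
    if emb.n_cells < 3:
        raise ValueError("need at least 3 cells to cluster")
    W = snn_graph(emb.coords, k_neighbors=k_neighbors)
    W_coo = sp.triu(W, k=1).tocoo()
    g = ig.Graph(n=emb.n_cells, edges=list(zip(W_coo.row.tolist(), W_coo.col.tolist())))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=W_coo.data.tolist(), resolution_parameter=float(resolution),
        seed=int(seed), n_iterations=2)
    labels = _relabel_by_size(np.array(part.membership))
    return ClusteringResult(labels=labels, resolution=float(resolution),
                            n_clusters=int(labels.max()) + 1, oob_error=float("nan"))


def oob_error(emb: Embedding, labels: Sequence[int], n_trees: int = 100,
              seed: int = 0) -> float:
    """Out-of-bag misclassification rate of a bagged decision-tree ensemble
    predicting cluster labels from the embedding coordinates.

    A single cluster is perfectly 'predictable'; its error is defined
    as 0 with a warning.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        warnings.warn("single cluster: OOB error defined as 0")
        return 0.0
    rf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                random_state=seed, n_jobs=1)
    with warnings.catch_warnings():
        # tiny datasets can leave a few samples with no OOB vote
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        rf.fit(emb.coords, y)
    return float(1.0 - rf.oob_score_)


def scan_resolutions(emb: Embedding, grid: Sequence[float],
                     selection_tolerance: float = 0.05, seed: int = 0,
                     k_neighbors: int = 20, n_trees: int = 100
                     ) -> Tuple[ClusteringResult, List[ClusteringResult]]:
    """Cluster and score every resolution on the grid, then select.

    Selection rule: among results with oob_error <= min(oob_error) +
    tolerance, take the maximum cluster count; ties break toward the
    lowest resolution.
    """
    grid = list(grid)
    if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be nonempty and strictly increasing")
    results: List[ClusteringResult] = []
    prev_k = 0
    for res in grid:
        r = cluster_at_resolution(emb, res, k_neighbors=k_neighbors, seed=seed)
        r.oob_error = oob_error(emb, r.labels, n_trees=n_trees, seed=seed)
        if r.n_clusters < prev_k:
            logger.info("cluster count decreased at resolution %.2f (%d -> %d)",
                        res, prev_k, r.n_clusters)
        prev_k = r.n_clusters
        results.append(r)
    return select_result(results, selection_tolerance), results


def select_result(results: Sequence[ClusteringResult],
                  selection_tolerance: float = 0.05) -> ClusteringResult:
    best_err = min(r.oob_error for r in results)
    band = [r for r in results if r.oob_error <= best_err + selection_tolerance]
    max_k = max(r.n_clusters for r in band)
    return min((r for r in band if r.n_clusters == max_k), key=lambda r: r.resolution)
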