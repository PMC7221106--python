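"""Pseudocell pooling, regulon inference, and regulon activity/specificity.

Pseudocells average the expression of 5-20 randomly chosen same-type
cells, stabilizing per-cell noise before scoring. Regulons (a TF plus
its targets) are inferred by thresholding Spearman correlation across
pseudocells, or supplied directly (e.g. from a GMT). The regulon
activity score (RAS) of a regulon in a pseudocell is the normalized
area under the recovery curve of its targets within the top ranked
fraction of genes. The regulon specificity score (RSS) for a cell type
is 1 - sqrt(JSD) between the RAS distribution over pseudocells and the
cell-type indicator distribution, with the Jensen-Shannon divergence in
log base 2 so both JSD and RSS lie in [0, 1].
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import jensenshannon
from scipy.stats import rankdata

from .containers import GeneMatrix


@dataclass
class Regulon:
    tf: str
    targets: List[str]
    weights: List[float] = field(default_factory=list)

    def __post_init__(self):
        if self.tf in self.targets:
            raise ValueError("a regulon's TF cannot be one of its own targets")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError("regulon targets must be unique")


@dataclass
class PseudocellMatrix:
    """Genes x pseudocells averaged expression with pool bookkeeping."""

    X: np.ndarray
    genes: np.ndarray
    cell_type: np.ndarray    # type label per pseudocell
    member_count: np.ndarray

    @property
    def n_pseudocells(self) -> int:
        return self.X.shape[1]


def make_pseudocells(matrix: GeneMatrix, labels: Sequence, pool_min: int = 5,
                     pool_max: int = 20, n_per_type: int = 50,
                     seed: int = 0) -> PseudocellMatrix:
    """Per type, ``n_per_type`` pseudocells, each the arithmetic mean of a
    uniformly drawn member set of size uniform in [pool_min, pool_max],
    drawn without replacement within the type. Types with fewer than
    ``pool_min`` cells are skipped with a warning."""
    if not (1 <= pool_min <= pool_max):
        raise ValueError("need 1 <= pool_min <= pool_max")
    if n_per_type <= 0:
        raise ValueError("n_per_type must be positive")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    X = matrix.X.tocsc() if sp.issparse(matrix.X) else np.asarray(matrix.X, dtype=float)
    cols, types, sizes = [], [], []
    for cl in np.unique(labels):
        idx = np.flatnonzero(labels == cl)
        if idx.size < pool_min:
            warnings.warn(f"type {cl!r} has {idx.size} cells (< {pool_min}); skipped")
            continue
        for _ in range(n_per_type):
            size = int(rng.integers(pool_min, min(pool_max, idx.size) + 1))
            members = rng.choice(idx, size=size, replace=False)
            sub = X[:, members]
            prof = np.asarray(sub.mean(axis=1)).ravel()
            cols.append(prof)
            types.append(cl)
            sizes.append(size)
    if not cols:
        raise ValueError("no cell type has enough cells to pool")
    return PseudocellMatrix(X=np.column_stack(cols), genes=matrix.genes.copy(),
                            cell_type=np.asarray(types, dtype=object),
                            member_count=np.asarray(sizes))


def infer_regulons(pc: PseudocellMatrix, tf_list: Sequence[str],
                   corr_threshold: float = 0.3,
                   max_targets: Optional[int] = None) -> List[Regulon]:
    """Targets = genes whose Spearman correlation with the TF across
    pseudocells meets ``corr_threshold``, capped at ``max_targets`` by
    descending correlation; TFs with no targets are dropped."""
    gene_set = set(pc.genes)
    missing = [t for t in tf_list if t not in gene_set]
    if missing:
        raise KeyError(f"TF(s) not in matrix: {missing[:5]}")
    R = np.apply_along_axis(rankdata, 1, pc.X)
    R -= R.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(R, axis=1)
    norm[norm <= 1e-12] = 1.0
    R /= norm[:, None]
    lookup = {g: i for i, g in enumerate(pc.genes)}
    out = []
    for tf in tf_list:
        i = lookup[tf]
        corr = R @ R[i]
        corr[i] = -np.inf  # never self
        cand = np.flatnonzero(corr >= corr_threshold)
        if cand.size == 0:
            continue
        cand = cand[np.argsort(-corr[cand], kind="stable")]
        if max_targets is not None:
            cand = cand[:max_targets]
        out.append(Regulon(tf=tf, targets=[pc.genes[j] for j in cand],
                           weights=[float(corr[j]) for j in cand]))
    return out


def regulon_activity(pc: PseudocellMatrix, regulon: Regulon,
                     top_fraction: float = 0.05) -> np.ndarray:
    """Recovery-curve area of the regulon's targets in each pseudocell.

    Genes are ranked by descending expression (ties by gene name); with
    m = ceil(top_fraction * n_genes), RAS is the area under the step
    curve of recovered targets over ranks 1..m, divided by the maximal
    achievable area, so RAS is in [0, 1].
    """
    if not (0 < top_fraction < 1):
        raise ValueError("top_fraction must lie in (0, 1)")
    if not regulon.targets:
        raise ValueError("empty regulon")
    n_genes = len(pc.genes)
    m = math.ceil(top_fraction * n_genes)
    tgt_idx = np.flatnonzero(np.isin(pc.genes, list(regulon.targets)))
    if tgt_idx.size == 0:
        raise ValueError("no regulon target present in matrix")
    R = len(regulon.targets)
    # maximal area: targets occupy ranks 1..R
    max_area = sum(min(x, R) for x in range(1, m + 1))
    name_order = np.argsort(pc.genes.astype(str), kind="stable")
    name_rank = np.empty(n_genes)
    name_rank[name_order] = np.arange(n_genes)
    ras = np.empty(pc.n_pseudocells)
    for j in range(pc.n_pseudocells):
        # stable sort on (-expression, gene name)
        order = np.lexsort((name_rank, -pc.X[:, j]))
        ranks = np.empty(n_genes, dtype=int)
        ranks[order] = np.arange(1, n_genes + 1)
        r = ranks[tgt_idx]
        in_top = r[r <= m]
        ras[j] = (m - in_top + 1).sum() / max_area
    return ras


def regulon_specificity(ras: np.ndarray, pseudocell_types: Sequence,
                        target_type) -> float:
    """RSS = 1 - sqrt(JSD) between the normalized RAS distribution and the
    target-type indicator distribution (JSD in log base 2)."""
    ras = np.asarray(ras, dtype=float)
    types = np.asarray(pseudocell_types)
    if ras.shape != types.shape:
        raise ValueError("ras and pseudocell_types must align")
    if ras.sum() <= 0:
        raise ValueError("RAS vector is all zero")
    p_r = ras / ras.sum()
    ind = (types == target_type).astype(float)
    if ind.sum() == 0:
        raise KeyError(f"type {target_type!r} not present")
    p_c = ind / ind.sum()
    # scipy returns the JS *distance*, i.e. sqrt(JSD)
    return float(1.0 - jensenshannon(p_r, p_c, base=2))


def rss_matrix(ras_table: pd.DataFrame, pseudocell_types: Sequence) -> pd.DataFrame:
    """RSS for every (regulon, cell type) pair.

    ``ras_table``: regulons x pseudocells RAS values.
    """
    types = np.asarray(pseudocell_types)
    out = {}
    for cl in np.unique(types):
        out[cl] = [regulon_specificity(ras_table.loc[r].values, types, cl)
                   for r in ras_table.index]
    return pd.DataFrame(out, index=ras_table.index)


def rank_regulons(rss: pd.DataFrame, cell_type) -> pd.DataFrame:
    """Regulons ordered by descending RSS for one cell type; ties break by
    regulon name."""
    if cell_type not in rss.columns:
        raise KeyError(f"cell type {cell_type!r} not in RSS matrix")
    col = rss[cell_type]
    order = sorted(rss.index, key=lambda r: (-col[r], str(r)))
    return pd.DataFrame({"regulon": order,
                         "rss": [float(col[r]) for r in order],
                         "rank": np.arange(1, len(order) + 1)})


def score_regulons(pc: PseudocellMatrix, regulons: Sequence[Regulon],
                   top_fraction: float = 0.05) -> "tuple[pd.DataFrame, pd.DataFrame]":
    """RAS for every regulon x pseudocell, and the derived RSS matrix."""
    rows = [regulon_activity(pc, r, top_fraction=top_fraction) for r in regulons]
    ras = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, pc.n_pseudocells)),
                       index=[r.tf for r in regulons])
    rss = rss_matrix(ras, pc.cell_type) if rows else pd.DataFrame()
    return ras, rss
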