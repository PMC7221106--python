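"""Metabolic regulation matrix between two time points, metabolic marker
sets, and disease-gene localization maps.

For each metabolic pathway n, a per-gene Wilcoxon test between the two
time points counts U_n genes up (avg logFC > 0, raw p < 0.05) and D_n
genes down in the later time point. Frequencies p(U_n) = U_n/(U_n+D_n)
and p(D_n) = D_n/(U_n+D_n) are assembled into vectors P^U and P^D,
each normalized to sum 1 over pathways, and the regulation matrix entry
is P^U - P^D: positive (red) means a predicted shift toward the
pathway, negative (blue) away from it. Pathways with U_n + D_n = 0 are
undefined (NA) and drop out of the normalization.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from . import markers as mk


@dataclass
class PathwayDECounts:
    pathway: str
    n_up: int    # avg logFC > 0 (later vs earlier), raw p < 0.05
    n_down: int  # avg logFC < 0, raw p < 0.05


def _combined(expr_later: ExpressionMatrix, expr_earlier: ExpressionMatrix,
              genes: Sequence[str]) -> "tuple[ExpressionMatrix, np.ndarray, np.ndarray]":
    """Stack the later/earlier cells gene-aligned on a shared gene subset."""
    common = [g for g in genes if g in set(expr_later.genes) and g in set(expr_earlier.genes)]
    skipped = [g for g in genes if g not in common]
    if skipped:
        warnings.warn(f"{len(skipped)} pathway gene(s) absent from matrix; skipped")
    if not common:
        return None, None, None
    A = expr_later.subset_genes(expr_later.gene_index(common)).dense()
    B = expr_earlier.subset_genes(expr_earlier.gene_index(common)).dense()
    X = np.hstack([A, B])
    cells = np.array([f"later_{i}" for i in range(A.shape[1])] +
                     [f"earlier_{i}" for i in range(B.shape[1])], dtype=object)
    merged = ExpressionMatrix(X, np.asarray(common, dtype=object), cells)
    later_mask = np.arange(X.shape[1]) < A.shape[1]
    return merged, later_mask, ~later_mask


def pathway_de_counts(expr_later: ExpressionMatrix, expr_earlier: ExpressionMatrix,
                      pathway_genes: Sequence[str], pathway_name: str = "",
                      alpha: float = 0.05) -> PathwayDECounts:
    """U/D counts for one pathway between two time points.

    Positive avg logFC means higher in the later time point. Pathway
    genes missing from either matrix are skipped with a warning.
    """
    merged, a_mask, b_mask = _combined(expr_later, expr_earlier, pathway_genes)
    if merged is None:
        return PathwayDECounts(pathway=pathway_name, n_up=0, n_down=0)
    rec = mk.de_two_groups(merged, a_mask, b_mask, min_pct=0.0, logfc_threshold=0.0)
    sig = rec[rec["p_value"] < alpha]
    return PathwayDECounts(pathway=pathway_name,
                           n_up=int((sig["avg_logfc"] > 0).sum()),
                           n_down=int((sig["avg_logfc"] < 0).sum()))


def regulation_frequencies(counts: PathwayDECounts) -> Optional[Tuple[float, float]]:
    """(p(U), p(D)) = (U, D) / (U + D); None when U + D = 0 (pathway dropped)."""
    total = counts.n_up + counts.n_down
    if total == 0:
        return None
    return counts.n_up / total, counts.n_down / total


def regulation_matrix(freqs_by_type: Dict[object, List[Tuple[str, Optional[Tuple[float, float]]]]]
                      ) -> pd.DataFrame:
    """Assemble the pathways x cell-types regulation matrix.

    ``freqs_by_type[cell_type]`` is a list of (pathway, (pU, pD) or None).
    Per type, the pU and pD vectors are each normalized to sum 1 over
    the non-NA pathways and subtracted; NA pathways stay NaN. A type
    whose pathways are all NA yields an all-NaN column with a warning.
    """
    pathways: List[str] = []
    for entries in freqs_by_type.values():
        for name, _ in entries:
            if name not in pathways:
                pathways.append(name)
    out = pd.DataFrame(np.nan, index=pathways, columns=list(freqs_by_type))
    for ct, entries in freqs_by_type.items():
        valid = [(name, f) for name, f in entries if f is not None]
        if not valid:
            warnings.warn(f"all pathways undefined for type {ct!r}")
            continue
        pu = np.array([f[0] for _, f in valid])
        pdn = np.array([f[1] for _, f in valid])
        pu = pu / pu.sum() if pu.sum() > 0 else np.zeros_like(pu)
        pdn = pdn / pdn.sum() if pdn.sum() > 0 else np.zeros_like(pdn)
        for (name, _), u, d in zip(valid, pu, pdn):
            out.loc[name, ct] = u - d
    return out


def regulation_matrix_for_types(expr_later: ExpressionMatrix,
                                expr_earlier: ExpressionMatrix,
                                labels_later: Sequence, labels_earlier: Sequence,
                                pathway_sets: Dict[str, List[str]],
                                cell_types: Optional[Sequence] = None,
                                alpha: float = 0.05
                                ) -> "tuple[pd.DataFrame, pd.DataFrame]":
    """Full two-timepoint statistic per cell type: U/D count table and the
    regulation matrix."""
    labels_later = np.asarray(labels_later)
    labels_earlier = np.asarray(labels_earlier)
    if cell_types is None:
        cell_types = sorted(set(labels_later) & set(labels_earlier))
    rows = []
    freqs = {}
    for ct in cell_types:
        lat = expr_later.subset_cells(np.flatnonzero(labels_later == ct))
        ear = expr_earlier.subset_cells(np.flatnonzero(labels_earlier == ct))
        entries = []
        for pname, genes in pathway_sets.items():
            c = pathway_de_counts(lat, ear, genes, pathway_name=pname, alpha=alpha)
            rows.append({"cell_type": ct, "pathway": pname,
                         "n_up": c.n_up, "n_down": c.n_down})
            entries.append((pname, regulation_frequencies(c)))
        freqs[ct] = entries
    return pd.DataFrame(rows), regulation_matrix(freqs)


def metabolic_markers(expr: ExpressionMatrix, labels: Sequence,
                      metabolic_sets: Dict[str, List[str]],
                      adj_alpha: float = 0.05
                      ) -> "tuple[Dict[object, List[str]], pd.DataFrame]":
    """Cell-type-specific metabolic marker sets (Wilcoxon one-vs-rest on the
    metabolic gene universe, adjusted p < ``adj_alpha``, positive only)
    plus pairwise overlap counts for set-diagram rendering."""
    universe = sorted({g for genes in metabolic_sets.values() for g in genes})
    rec = mk.find_all_markers(expr, labels, min_pct=0.0, logfc_threshold=0.0,
                              genes=universe, only_positive=True)
    rec = rec[rec["adj_p"] < adj_alpha]
    sets: Dict[object, List[str]] = {}
    for cl in np.unique(np.asarray(labels)):
        sets[cl] = sorted(rec.loc[rec["cluster"] == cl, "gene"].tolist())
    types = list(sets)
    overlaps = pd.DataFrame(0, index=types, columns=types)
    for a in types:
        for b in types:
            overlaps.loc[a, b] = len(set(sets[a]) & set(sets[b]))
    return sets, overlaps


def disease_map(expr: ExpressionMatrix, labels: Sequence,
                disease_sets: Dict[str, List[str]]
                ) -> Dict[str, "tuple[pd.DataFrame, List[str]]"]:
    """Per disease class: cluster-averaged z-score matrix for the genes
    present in the matrix, plus the list of absent genes."""
    gene_set = set(expr.genes)
    out = {}
    for cls, genes in disease_sets.items():
        present = [g for g in genes if g in gene_set]
        absent = [g for g in genes if g not in gene_set]
        if present:
            Z = mk.celltype_zscore_matrix(expr, labels, present)
        else:
            Z = pd.DataFrame()
        out[cls] = (Z, absent)
    return out
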