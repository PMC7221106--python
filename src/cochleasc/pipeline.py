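"""End-to-end pipeline: chains the stages qc -> cluster -> markers and the
optional trajectory / regulons / metabolic / disease-map branches, writing
one CSV or MatrixMarket artifact per result. Deterministic given the seed.

Each stage logs one line to stderr with its input/output dimensions and
the seed in force.
"""
from __future__ import annotations

import logging
import os
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import clustering as cl
from . import io as cio
from . import markers as mk
from . import metabolic as mb
from . import qc
from . import regulons as rg
from . import simulate as sim
from . import trajectory as tj
from .config import GeneratorConfig, PipelineConfig, load_preset
from .containers import CountMatrix, ExpressionMatrix, LabeledDataset

logger = logging.getLogger("cochleasc")

HEADER = "# produced by cochleasc {stage}; seed={seed}; units={units}\n"


class PipelineError(RuntimeError):
    pass


def _write_csv(df: pd.DataFrame, path: str, stage: str, seed: int, units: str,
               index_label: Optional[str] = None) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        fh.write(HEADER.format(stage=stage, seed=seed, units=units))
        df.to_csv(fh, index=index_label is not None, index_label=index_label,
                  float_format="%.10g")


def simulate_stage(gen_config: GeneratorConfig, out_dir: str, seed: int,
                   preset: Optional[str] = None) -> LabeledDataset:
    """Generate a labeled dataset (with QC violators when configured) and
    write the count matrix plus ground-truth tables."""
    if preset in ("trajectory",):
        ds = sim.generate_trajectory(gen_config, seed=seed)
    elif preset in ("regulons",):
        ds = sim.generate_regulon_data(gen_config, seed=seed)
    elif preset in ("timepoints",):
        ds1, ds2 = sim.generate_timepoint_pair(gen_config, seed=seed)
        save_dataset(ds1, os.path.join(out_dir, "t_early"), seed)
        save_dataset(ds2, os.path.join(out_dir, "t_late"), seed)
        logger.info("stage=simulate preset=timepoints seed=%d cells=%d+%d genes=%d",
                    seed, ds1.counts.n_cells, ds2.counts.n_cells, ds1.counts.n_genes)
        return ds2
    else:
        ds = sim.generate_celltypes(gen_config, seed=seed)
        if gen_config.qc_outlier_fractions:
            ds = sim.inject_qc_outliers(ds, gen_config.qc_outlier_fractions,
                                        seed=seed + 1)
    save_dataset(ds, out_dir, seed)
    logger.info("stage=simulate seed=%d cells=%d genes=%d",
                seed, ds.counts.n_cells, ds.counts.n_genes)
    return ds


def save_dataset(ds: LabeledDataset, out_dir: str, seed: int) -> None:
    cio.write_10x_mtx(ds.counts, out_dir)
    meta = pd.DataFrame({"cell_type": ds.cell_type}, index=pd.Index(ds.counts.cells, name="cell"))
    if ds.true_pseudotime is not None:
        meta["true_pseudotime"] = ds.true_pseudotime
    meta["qc_violations"] = [";".join(ds.qc_violations.get(c, [])) for c in ds.counts.cells]
    _write_csv(meta, os.path.join(out_dir, "cell_truth.csv"), "simulate", seed,
               "labels", index_label="cell")
    if ds.true_markers:
        _write_csv(pd.DataFrame(sorted(ds.true_markers.items()),
                                columns=["gene", "cell_type"]),
                   os.path.join(out_dir, "true_markers.csv"), "simulate", seed, "labels")
    if ds.true_module:
        _write_csv(pd.DataFrame(sorted(ds.true_module.items()),
                                columns=["gene", "module"]),
                   os.path.join(out_dir, "true_modules.csv"), "simulate", seed, "labels")
    if ds.true_regulons:
        cio.write_gmt({tf: [tf] + info["targets"] for tf, info in ds.true_regulons.items()},
                      os.path.join(out_dir, "true_regulons.gmt"))
    if ds.true_pathway_shift:
        rows = [{"pathway": p, "n_up": v["n_up"], "n_down": v["n_down"],
                 "direction": v["direction"]} for p, v in ds.true_pathway_shift.items()]
        _write_csv(pd.DataFrame(rows), os.path.join(out_dir, "true_pathway_shift.csv"),
                   "simulate", seed, "gene counts")


def load_dataset(in_dir: str) -> "tuple[CountMatrix, Optional[np.ndarray]]":
    counts = cio.read_10x_mtx(in_dir)
    truth = os.path.join(in_dir, "cell_truth.csv")
    labels = None
    if os.path.exists(truth):
        meta = pd.read_csv(truth, comment="#", index_col=0)
        labels = meta.loc[counts.cells, "cell_type"].values
    return counts, labels


def qc_stage(counts: CountMatrix, config: PipelineConfig, out_dir: str
             ) -> "tuple[CountMatrix, qc.QCReport]":
    before = (counts.n_genes, counts.n_cells)
    counts = qc.filter_genes(counts, config.qc.min_cells_per_gene)
    report = qc.filter_cells(counts, config.qc)
    kept = qc.apply_cell_filter(counts, report)
    _write_csv(report.table, os.path.join(out_dir, "qc_report.csv"), "qc",
               config.seed, "per-cell QC metrics", index_label="cell")
    cio.write_10x_mtx(kept, os.path.join(out_dir, "filtered"))
    logger.info("stage=qc seed=%d in=%dx%d out=%dx%d", config.seed,
                before[0], before[1], kept.n_genes, kept.n_cells)
    return kept, report


def normalize_stage(counts: CountMatrix, config: PipelineConfig) -> np.ndarray:
    expr = qc.normalize_log(counts, config.scale_factor)
    cov = qc.standard_covariates(counts)
    scaled = qc.regress_and_scale(expr, cov, clip=config.clip)
    logger.info("stage=normalize seed=%d genes=%d cells=%d", config.seed,
                expr.n_genes, expr.n_cells)
    return scaled


def cluster_stage(counts: CountMatrix, config: PipelineConfig, out_dir: str
                  ) -> "tuple[cl.ClusteringResult, cl.Embedding]":
    scaled = normalize_stage(counts, config)
    emb = cl.reduce_dims(scaled, config.clustering.n_components)
    selected, scan = cl.scan_resolutions(
        emb, config.clustering.resolution_grid,
        selection_tolerance=config.clustering.selection_tolerance,
        seed=config.seed, k_neighbors=config.clustering.k_neighbors,
        n_trees=config.clustering.n_trees)
    _write_csv(pd.DataFrame([{"resolution": r.resolution, "n_clusters": r.n_clusters,
                              "oob_error": r.oob_error} for r in scan]),
               os.path.join(out_dir, "resolution_scan.csv"), "cluster",
               config.seed, "count / error rate")
    _write_csv(pd.DataFrame({"cluster": selected.labels},
                            index=pd.Index(counts.cells, name="cell")),
               os.path.join(out_dir, "clusters.csv"), "cluster", config.seed,
               "cluster ids", index_label="cell")
    logger.info("stage=cluster seed=%d cells=%d selected_resolution=%.2f k=%d oob=%.4f",
                config.seed, emb.n_cells, selected.resolution,
                selected.n_clusters, selected.oob_error)
    return selected, emb


def markers_stage(counts: CountMatrix, labels, config: PipelineConfig,
                  out_dir: str) -> pd.DataFrame:
    expr = qc.normalize_log(counts, config.scale_factor)
    rec = mk.find_all_markers(expr, labels, min_pct=config.markers.min_pct,
                              logfc_threshold=config.markers.logfc_threshold,
                              log2=config.markers.log2)
    top = mk.top_markers(rec, config.markers.top_n)
    _write_csv(rec, os.path.join(out_dir, "markers.csv"), "markers", config.seed,
               "natural-log fold change" if not config.markers.log2 else "log2 fold change")
    _write_csv(top, os.path.join(out_dir, "top_markers.csv"), "markers",
               config.seed, "natural-log fold change")
    logger.info("stage=markers seed=%d clusters=%d records=%d", config.seed,
                len(np.unique(np.asarray(labels))), len(rec))
    return rec


def trajectory_stage(counts: CountMatrix, labels, emb: cl.Embedding,
                     config: PipelineConfig, out_dir: str) -> tj.PhaseModules:
    expr = qc.normalize_log(counts, config.scale_factor)
    # ordering backbone: a coarse partition at a fixed resolution, so the
    # centroid tree stays simple regardless of the fine typology
    backbone = cl.cluster_at_resolution(emb, config.trajectory.ordering_resolution,
                                        k_neighbors=config.clustering.k_neighbors,
                                        seed=config.seed)
    labels = backbone.labels
    root = config.trajectory.root_cluster
    if root is None:
        if config.trajectory.progenitor_markers:
            root = tj.pick_root_cluster(expr, labels, config.trajectory.progenitor_markers)
        else:
            root = np.unique(np.asarray(labels))[0]
    traj = tj.order_cells(emb, labels, root)
    de = tj.de_along_pseudotime(expr, traj, fdr=config.trajectory.fdr)
    sig = de.loc[de["significant"], "gene"].tolist()
    modules = tj.cluster_gene_trends(expr, traj, sig, k=config.trajectory.n_modules,
                                     seed=config.seed)
    _write_csv(pd.DataFrame({"pseudotime": traj.pseudotime, "branch": traj.branch},
                            index=pd.Index(counts.cells, name="cell")),
               os.path.join(out_dir, "pseudotime.csv"), "trajectory", config.seed,
               "normalized arc length", index_label="cell")
    _write_csv(de, os.path.join(out_dir, "pseudotime_de.csv"), "trajectory",
               config.seed, "p / BH q values")
    _write_csv(pd.DataFrame(sorted(modules.assignment.items()),
                            columns=["gene", "module"]),
               os.path.join(out_dir, "phase_modules.csv"), "trajectory",
               config.seed, "module labels")
    _write_csv(modules.trends, os.path.join(out_dir, "trend_grid.csv"), "trajectory",
               config.seed, "z-scored smoothed expression", index_label="gene")
    logger.info("stage=trajectory seed=%d cells=%d sig_genes=%d k=%d", config.seed,
                counts.n_cells, len(sig), modules.k)
    return modules


def regulons_stage(counts: CountMatrix, labels, config: PipelineConfig,
                   out_dir: str, tf_list=None, regulon_sets=None) -> pd.DataFrame:
    expr = qc.normalize_log(counts, config.scale_factor)
    pc = rg.make_pseudocells(expr, labels, pool_min=config.regulons.pool_min,
                             pool_max=config.regulons.pool_max,
                             n_per_type=config.regulons.n_per_type, seed=config.seed)
    if regulon_sets:
        regs = [rg.Regulon(tf=name, targets=[g for g in genes if g != name])
                for name, genes in regulon_sets.items()]
    else:
        if tf_list is None:
            tf_list = [g for g in counts.genes if str(g).startswith("tf_")]
        if not tf_list:
            raise PipelineError("regulons: no TF list given and no tf_* genes found")
        regs = rg.infer_regulons(pc, tf_list, corr_threshold=config.regulons.corr_threshold,
                                 max_targets=config.regulons.max_targets)
    ras, rss = rg.score_regulons(pc, regs, top_fraction=config.regulons.top_fraction)
    _write_csv(ras, os.path.join(out_dir, "ras.csv"), "regulons", config.seed,
               "recovery-curve AUC in [0,1]", index_label="regulon")
    _write_csv(rss, os.path.join(out_dir, "rss.csv"), "regulons", config.seed,
               "1 - sqrt(JSD) in [0,1]", index_label="regulon")
    ranks = pd.concat([rg.rank_regulons(rss, ct).assign(cell_type=ct)
                       for ct in rss.columns], ignore_index=True)
    _write_csv(ranks, os.path.join(out_dir, "regulon_ranks.csv"), "regulons",
               config.seed, "rank by RSS")
    logger.info("stage=regulons seed=%d pseudocells=%d regulons=%d", config.seed,
                pc.n_pseudocells, len(regs))
    return rss


def metabolic_stage(counts_early: CountMatrix, labels_early,
                    counts_late: CountMatrix, labels_late,
                    pathway_sets: Dict[str, list], config: PipelineConfig,
                    out_dir: str) -> pd.DataFrame:
    expr_e = qc.normalize_log(counts_early, config.scale_factor)
    expr_l = qc.normalize_log(counts_late, config.scale_factor)
    table, matrix = mb.regulation_matrix_for_types(
        expr_l, expr_e, labels_late, labels_early, pathway_sets)
    _write_csv(table, os.path.join(out_dir, "pathway_de_counts.csv"), "metabolic",
               config.seed, "DE gene counts")
    _write_csv(matrix, os.path.join(out_dir, "regulation_matrix.csv"), "metabolic",
               config.seed, "normalized p(U)-p(D), red>0 blue<0", index_label="pathway")
    logger.info("stage=metabolic seed=%d pathways=%d types=%d", config.seed,
                matrix.shape[0], matrix.shape[1])
    return matrix


def disease_map_stage(counts: CountMatrix, labels, disease_sets: Dict[str, list],
                      config: PipelineConfig, out_dir: str) -> None:
    expr = qc.normalize_log(counts, config.scale_factor)
    maps = mb.disease_map(expr, labels, disease_sets)
    for cls, (Z, absent) in maps.items():
        _write_csv(Z, os.path.join(out_dir, f"disease_map_{cls}.csv"), "disease-map",
                   config.seed, "cluster-averaged z-scores", index_label="gene")
        with open(os.path.join(out_dir, f"disease_map_{cls}_absent.txt"), "w") as fh:
            fh.writelines(f"{g}\n" for g in absent)
    logger.info("stage=disease-map seed=%d classes=%d", config.seed, len(maps))


def run_pipeline(config: PipelineConfig,
                 gen_config: Optional[GeneratorConfig] = None,
                 stages: Sequence = ("qc", "cluster", "markers"),
                 gene_sets: Optional[Dict[str, list]] = None) -> dict:
    """Run the configured stages in order, writing artifacts to
    ``config.out_dir``. Returns the in-memory results keyed by stage."""
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    results: dict = {}
    try:
        if config.preset:
            _, gcfg = load_preset(config.preset)
            gcfg = gen_config or gcfg
            gcfg.seed = config.seed
            ds = simulate_stage(gcfg, os.path.join(out, "simulated"), config.seed,
                                preset=config.preset)
            counts, labels = ds.counts, ds.cell_type
            results["simulate"] = ds
        elif config.input_dir:
            counts, labels = load_dataset(config.input_dir)
        else:
            raise PipelineError("config must name an input_dir or a preset")
    except PipelineError:
        raise
    except Exception as e:  # pragma: no cover - defensive
        raise PipelineError(f"simulate: {e}") from e

    stage = None
    try:
        if "qc" in stages:
            stage = "qc"
            label_by_cell = (dict(zip(counts.cells, labels))
                             if labels is not None else None)
            counts, report = qc_stage(counts, config, out)
            if label_by_cell is not None:
                labels = np.array([label_by_cell[c] for c in counts.cells], dtype=object)
            results["qc"] = report
        if "cluster" in stages:
            stage = "cluster"
            selected, emb = cluster_stage(counts, config, out)
            results["cluster"], results["embedding"] = selected, emb
            cluster_labels = selected.labels
        else:
            cluster_labels = labels
        if "markers" in stages:
            stage = "markers"
            results["markers"] = markers_stage(counts, cluster_labels, config, out)
        if "trajectory" in stages:
            stage = "trajectory"
            emb = results.get("embedding")
            if emb is None:
                scaled = normalize_stage(counts, config)
                emb = cl.reduce_dims(scaled, config.clustering.n_components)
            results["trajectory"] = trajectory_stage(counts, cluster_labels, emb,
                                                     config, out)
        if "regulons" in stages:
            stage = "regulons"
            results["regulons"] = regulons_stage(counts, labels if labels is not None
                                                 else cluster_labels, config, out,
                                                 regulon_sets=gene_sets)
        if "disease-map" in stages:
            stage = "disease-map"
            if not gene_sets:
                raise PipelineError("disease-map: a gene-set GMT is required")
            disease_map_stage(counts, cluster_labels, gene_sets, config, out)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"{stage}: {e}") from e
    return results
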