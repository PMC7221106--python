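"""Pipeline and generator configuration.

Defaults equal the published analysis parameters: QC bounds 200/1500
genes/UMI (low) and 3000/15,000 (high), 5% mitochondrial and stress-gene
UMI shares, 10-cell gene filter, resolution grid 0.2-2.4 in 0.2 steps,
marker gates min.pct = 0.25 and log-fold threshold 0.25, pseudotime FDR
0.1 with four trend modules, and 5-20-cell pseudocell pools.

Configs load from YAML; CLI flags override config keys. Named presets
ship as packaged YAML files.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional

import numpy as np
import yaml

RESOLUTION_GRID_DEFAULT: List[float] = [round(0.2 * i, 1) for i in range(1, 13)]

PRESET_NAMES = ("p1", "p7", "trajectory", "timepoints", "regulons")


@dataclass
class QCThresholds:
    """Cell/gene quality-control bounds.

    A cell is excluded when ANY bound is violated (the disjunctive
    reading; set ``conjunctive_pairs`` to require both members of the
    low or high gene/UMI pair to fail together).
    """

    min_genes: int = 200
    min_umi: int = 1500
    max_genes: int = 3000
    max_umi: int = 15000
    max_mito_frac: float = 0.05
    max_stress_frac: float = 0.05
    min_cells_per_gene: int = 10
    conjunctive_pairs: bool = False

    def validate(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if self.min_umi >= self.max_umi:
            raise ValueError("min_umi must be < max_umi")
        for name in ("max_mito_frac", "max_stress_frac"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if min(self.min_genes, self.min_umi, self.min_cells_per_gene) < 0:
            raise ValueError("thresholds must be nonnegative")


@dataclass
class ClusterSettings:
    resolution_grid: List[float] = field(default_factory=lambda: list(RESOLUTION_GRID_DEFAULT))
    selection_tolerance: float = 0.05
    n_components: int = 20
    k_neighbors: int = 20
    n_trees: int = 100

    def validate(self) -> None:
        g = self.resolution_grid
        if not g or any(b <= a for a, b in zip(g, g[1:])):
            raise ValueError("resolution_grid must be nonempty and strictly increasing")
        if self.selection_tolerance < 0:
            raise ValueError("selection_tolerance must be nonnegative")


@dataclass
class MarkerSettings:
    min_pct: float = 0.25
    logfc_threshold: float = 0.25
    top_n: int = 25
    exclusive_f_on: float = 0.3
    exclusive_f_off: float = 0.1
    log2: bool = False  # report avgLogFC in log2 rather than natural log

    def validate(self) -> None:
        for name in ("min_pct", "exclusive_f_on", "exclusive_f_off"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class TrajectorySettings:
    fdr: float = 0.1
    n_modules: "int | str" = 4  # integer or "auto"
    root_cluster: Optional[str] = None
    progenitor_markers: List[str] = field(default_factory=list)
    # pseudotime ordering uses a coarse cluster backbone, independent of the
    # fine typology chosen by the resolution scan
    ordering_resolution: float = 1.0

    def validate(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")
        if self.n_modules != "auto" and int(self.n_modules) < 2:
            raise ValueError("n_modules must be >= 2 or 'auto'")


@dataclass
class RegulonSettings:
    pool_min: int = 5
    pool_max: int = 20
    n_per_type: int = 50
    top_fraction: float = 0.05
    corr_threshold: float = 0.3
    max_targets: Optional[int] = None

    def validate(self) -> None:
        if not (1 <= self.pool_min <= self.pool_max):
            raise ValueError("pool bounds must satisfy 1 <= pool_min <= pool_max")
        if not (0 < self.top_fraction < 1):
            raise ValueError("top_fraction must lie in (0, 1)")


@dataclass
class PipelineConfig:
    qc: QCThresholds = field(default_factory=QCThresholds)
    clustering: ClusterSettings = field(default_factory=ClusterSettings)
    markers: MarkerSettings = field(default_factory=MarkerSettings)
    trajectory: TrajectorySettings = field(default_factory=TrajectorySettings)
    regulons: RegulonSettings = field(default_factory=RegulonSettings)
    scale_factor: float = 1e4
    clip: float = 10.0
    seed: int = 0
    input_dir: Optional[str] = None
    preset: Optional[str] = None
    out_dir: str = "cochleasc_out"

    def validate(self) -> None:
        for sub in (self.qc, self.clustering, self.markers, self.trajectory, self.regulons):
            sub.validate()


@dataclass
class GeneratorConfig:
    """Conditions for the synthetic cochlear-epithelium generator."""

    n_genes: int = 2000
    n_types: int = 15
    n_cells_per_type: "int | List[int]" = 100
    markers_per_type: int = 25
    marker_fold: float = 6.0
    # genes expressed essentially only in their own type (the
    # exclusive-expression screen's planted targets)
    exclusive_per_type: int = 5
    exclusive_off_factor: float = 0.003
    base_mean: float = 2.0
    dispersion: float = 2.0
    lib_size_mu: float = 0.0
    lib_size_sigma: float = 0.25
    mito_gene_count: int = 10
    stress_gene_count: int = 10
    qc_outlier_fractions: dict = field(default_factory=dict)
    trajectory: dict = field(default_factory=lambda: {
        "n_cells": 600,
        "n_modules": 4,
        "genes_per_module": 50,
        "templates": ["early_decreasing", "transient_peak", "mid_rising", "late_rising"],
    })
    regulons: dict = field(default_factory=lambda: {
        "n_tfs": 10,
        "targets_per_tf": 20,
        "active_type_per_tf": None,  # default: cycle over types
        "coupling_strength": 0.8,
    })
    pathways: dict = field(default_factory=lambda: {
        "names": ["glycolysis", "tca", "oxphos", "ppp", "fao", "aa_metab"],
        "genes_per_pathway": 20,
        # per-pathway fractions: developmental shifts differ across pathways,
        # which is what the regulation matrix is built to contrast
        "up_frac": [0.8, 0.1, 0.7, 0.2, 0.75, 0.15],
        "down_frac": [0.1, 0.8, 0.2, 0.7, 0.15, 0.75],
        "shift_logfc": 0.6931471805599453,  # ln 2
    })
    seed: int = 0

    def cells_per_type(self) -> List[int]:
        if isinstance(self.n_cells_per_type, int):
            return [self.n_cells_per_type] * self.n_types
        if len(self.n_cells_per_type) != self.n_types:
            raise ValueError("n_cells_per_type list length must equal n_types")
        return list(self.n_cells_per_type)

    def validate(self) -> None:
        if self.n_types * (self.markers_per_type + self.exclusive_per_type) > self.n_genes:
            raise ValueError("n_types * (markers_per_type + exclusive_per_type) exceeds n_genes")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")
        if any(n < 0 for n in self.cells_per_type()):
            raise ValueError("cell counts must be nonnegative")
        reg = self.regulons
        if reg.get("n_tfs", 0) * reg.get("targets_per_tf", 0) > self.n_genes / 2:
            raise ValueError("regulon genes would exceed half the genome")
        pw = self.pathways
        n_pw = len(pw.get("names", []))
        up = np.broadcast_to(np.asarray(pw.get("up_frac", 0.0), dtype=float), n_pw)
        down = np.broadcast_to(np.asarray(pw.get("down_frac", 0.0), dtype=float), n_pw)
        if np.any(up + down > 1):
            raise ValueError("up_frac + down_frac must be <= 1 for every pathway")
        if pw.get("shift_logfc", 1.0) <= 0:
            raise ValueError("shift_logfc must be positive")
        for rule, frac in self.qc_outlier_fractions.items():
            if not (0 <= frac <= 1):
                raise ValueError(f"outlier fraction for {rule} must lie in [0, 1]")


def _build(cls, data: dict):
    """Recursively build a dataclass from a nested mapping, rejecting unknown keys."""
    names = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in names:
            raise KeyError(f"unknown {cls.__name__} key: {key!r}")
        ftype = names[key].default_factory() if callable(names[key].default_factory or 0) else None
        if dataclasses.is_dataclass(ftype) and isinstance(value, dict):
            kwargs[key] = _build(type(ftype), value)
        elif isinstance(ftype, dict) and isinstance(value, dict):
            merged = dict(ftype)
            merged.update(value)
            kwargs[key] = merged
        else:
            kwargs[key] = value
    return cls(**kwargs)


def pipeline_config_from_dict(data: dict) -> PipelineConfig:
    cfg = _build(PipelineConfig, data or {})
    cfg.validate()
    return cfg


def generator_config_from_dict(data: dict) -> GeneratorConfig:
    cfg = _build(GeneratorConfig, data or {})
    cfg.validate()
    return cfg


def load_config(path: str) -> "tuple[PipelineConfig, GeneratorConfig]":
    """Load a YAML config file with optional ``pipeline:`` and ``generator:`` sections."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return (pipeline_config_from_dict(data.get("pipeline", {})),
            generator_config_from_dict(data.get("generator", {})))


def load_preset(name: str) -> "tuple[PipelineConfig, GeneratorConfig]":
    """Load one of the packaged presets: p1, p7, trajectory, timepoints, regulons."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    text = resources.files("cochleasc").joinpath(f"presets/{name}.yaml").read_text()
    data = yaml.safe_load(text) or {}
    return (pipeline_config_from_dict(data.get("pipeline", {})),
            generator_config_from_dict(data.get("generator", {})))
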