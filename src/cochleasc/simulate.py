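"""Synthetic cochlear-epithelium count generator with planted ground truth.

Counts follow a negative binomial law: for gene g in cell c,

    count ~ NB(mean = m_g * f(g, c) * l_c, inverse-dispersion r)

where ``m_g`` is a gene-level base mean (gamma-distributed across genes),
``f`` multiplies marker genes of the cell's type by ``marker_fold`` (and
carries any planted trajectory/regulon/pathway effect), and ``l_c`` is a
log-normal cell library-size factor. Mitochondrial and stress genes
(named ``mt-*`` / ``stress-*`` so QC can find them by convention)
receive a per-cell UMI share drawn around 2% for normal cells. Separate
entry points plant a differentiation continuum with temporal gene
modules, TF-driven regulons, QC-violating cells, and two-timepoint
pathway shifts; every planted entity is recorded in the returned
:class:`~cochleasc.containers.LabeledDataset`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .config import GeneratorConfig
from .containers import CountMatrix, LabeledDataset

QC_RULES = ("low_complexity", "high_complexity", "high_mito", "high_stress")

# Temporal templates (exponent on marker_fold as a function of pseudotime).
# Shapes are spaced so the four programs are roughly equidistant in trend
# space, as the four observed outer-hair-cell phases are: progenitor genes
# that switch off, a transient early-differentiation pulse, genes rising
# through mid-differentiation that subside terminally, and terminal
# maturation genes that switch on at the very end.
TRAJECTORY_TEMPLATES = {
    "early_decreasing": lambda t: (1.0 - t) ** 2,
    "transient_peak": lambda t: np.exp(-(((t - 0.35) / 0.10) ** 2)),
    "mid_rising": lambda t: np.exp(-(((t - 0.68) / 0.13) ** 2)),
    "late_rising": lambda t: 1.0 / (1.0 + np.exp(-(t - 0.88) * 30.0)),
}


# ---------------------------------------------------------------- structure

@dataclass
class _Structure:
    """Structural randomness shared between related draws (e.g. timepoints)."""

    names: np.ndarray        # all gene names, regular first
    n_reg: int
    base: np.ndarray         # regular-gene base means
    marker_by_type: np.ndarray  # n_types x markers_per_type regular-gene indices
    exclusive_by_type: np.ndarray  # n_types x exclusive_per_type indices
    type_names: List[str]
    per_type: List[int]


def _gene_names(cfg: GeneratorConfig) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_reg = cfg.n_genes - cfg.mito_gene_count - cfg.stress_gene_count
    if n_reg <= 0:
        raise ValueError("n_genes must exceed mito_gene_count + stress_gene_count")
    regular = np.array([f"g{i:05d}" for i in range(n_reg)], dtype=object)
    mito = np.array([f"mt-{i:02d}" for i in range(cfg.mito_gene_count)], dtype=object)
    stress = np.array([f"stress-{i:02d}" for i in range(cfg.stress_gene_count)], dtype=object)
    return regular, mito, stress


def _base_means(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    # Gamma(0.5) across genes: a skewed mean profile with many low expressors.
    return np.maximum(rng.gamma(0.5, scale / 0.5, size=n), 1e-3)


def _celltype_structure(config: GeneratorConfig, rng: np.random.Generator) -> _Structure:
    regular, mito, stress = _gene_names(config)
    n_reg = len(regular)
    base = _base_means(rng, n_reg, config.base_mean)
    n_mark = config.n_types * config.markers_per_type
    n_excl = config.n_types * config.exclusive_per_type
    picked = rng.choice(n_reg, size=n_mark + n_excl, replace=False)
    marker_idx, excl_idx = picked[:n_mark], picked[n_mark:]
    # markers get a dependable baseline so the fold is detectable
    base[marker_idx] = config.base_mean * rng.uniform(0.5, 1.5, size=marker_idx.size)
    base[excl_idx] = config.base_mean * rng.uniform(0.75, 1.25, size=excl_idx.size)
    return _Structure(
        names=np.concatenate([regular, mito, stress]), n_reg=n_reg, base=base,
        marker_by_type=marker_idx.reshape(config.n_types, config.markers_per_type),
        exclusive_by_type=excl_idx.reshape(config.n_types, config.exclusive_per_type),
        type_names=[f"type_{i + 1:02d}" for i in range(config.n_types)],
        per_type=config.cells_per_type())


# ------------------------------------------------------------------- draws

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, r: float) -> np.ndarray:
    p = r / (r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(r, p)


def _draw_counts(config: GeneratorConfig, s: _Structure, rng: np.random.Generator,
                 gene_log_mult: Optional[np.ndarray] = None,
                 cellwise_mult: Optional[np.ndarray] = None,
                 low_noise_genes: Optional[np.ndarray] = None,
                 cell_prefix: str = "cell") -> Tuple[CountMatrix, np.ndarray]:
    """One NB draw from the structure; optional per-gene or per-(gene,cell)
    multipliers act on the regular-gene means before drawing."""
    n_cells = int(sum(s.per_type))
    cell_type = np.repeat(s.type_names, s.per_type)
    cells = np.array([f"{cell_prefix}_{i + 1:05d}" for i in range(n_cells)], dtype=object)
    lib = rng.lognormal(config.lib_size_mu, config.lib_size_sigma, size=n_cells)

    all_excl = s.exclusive_by_type.ravel()
    mean_reg = np.empty((s.n_reg, n_cells))
    start = 0
    for t, n_t in enumerate(s.per_type):
        fold = np.ones(s.n_reg)
        if all_excl.size:
            fold[all_excl] = config.exclusive_off_factor
            fold[s.exclusive_by_type[t]] = 1.0
        fold[s.marker_by_type[t]] = config.marker_fold
        mean_reg[:, start:start + n_t] = (s.base * fold)[:, None]
        start += n_t
    if gene_log_mult is not None:
        mean_reg *= np.exp(np.asarray(gene_log_mult, dtype=float))[:, None]
    if cellwise_mult is not None:
        mean_reg *= cellwise_mult
    mean_reg *= lib[None, :]

    counts_reg = _nb_draw(rng, mean_reg, config.dispersion)
    if low_noise_genes is not None and low_noise_genes.size:
        # factor-model genes: the shared latent factor carries the biological
        # variability, so the conditional draw is near-Poisson
        counts_reg[low_noise_genes, :] = _nb_draw(
            rng, mean_reg[low_noise_genes, :], 10.0 * config.dispersion)
    n_mito = config.mito_gene_count
    n_stress = config.stress_gene_count
    regular_total = mean_reg.sum(axis=0)
    # normal cells sit near a 2% mito/stress UMI share, clearly below the 5%
    # QC bound: tight Beta share and mildly dispersed counts (these model
    # stably expressed housekeeping-type genes, not bursty ones)
    m_share = rng.beta(40, 1960, size=n_cells)
    s_share = rng.beta(40, 1960, size=n_cells)
    rest = 1.0 - m_share - s_share
    mito_mean = np.repeat(((m_share / rest) * regular_total / max(n_mito, 1))[None, :],
                          n_mito, axis=0)
    stress_mean = np.repeat(((s_share / rest) * regular_total / max(n_stress, 1))[None, :],
                            n_stress, axis=0)
    counts_mito = _nb_draw(rng, mito_mean, 10.0 * config.dispersion)
    counts_stress = _nb_draw(rng, stress_mean, 10.0 * config.dispersion)
    X = sp.csr_matrix(np.vstack([counts_reg, counts_mito, counts_stress]).astype(np.int64))
    return CountMatrix(X, s.names.copy(), cells), cell_type


# -------------------------------------------------------------- public ops

def generate_celltypes(config: GeneratorConfig, seed: Optional[int] = None) -> LabeledDataset:
    """Discrete cell-type expression programs: ``markers_per_type`` genes per
    type are upregulated ``marker_fold``-fold in that type only."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    s = _celltype_structure(config, rng)
    counts, cell_type = _draw_counts(config, s, rng)
    true_markers = {s.names[g]: s.type_names[t]
                    for t in range(config.n_types) for g in s.marker_by_type[t]}
    true_exclusive = {s.names[g]: s.type_names[t]
                      for t in range(config.n_types) for g in s.exclusive_by_type[t]}
    true_markers.update(true_exclusive)
    return LabeledDataset(counts=counts, cell_type=cell_type,
                          true_markers=true_markers, true_exclusive=true_exclusive)


def inject_qc_outliers(ds: LabeledDataset, fractions: Dict[str, float],
                       seed: int = 0) -> LabeledDataset:
    """Modify disjoint random cell subsets so each violates one named QC rule.

    Rules: ``low_complexity`` (<200 detected genes and <1500 UMI),
    ``high_complexity`` (>15,000 UMI), ``high_mito`` / ``high_stress``
    (UMI share pushed to ~8%, above the 5% bound).
    """
    for rule, frac in fractions.items():
        if rule not in QC_RULES:
            raise ValueError(f"unknown QC rule {rule!r}; choose from {QC_RULES}")
        if not (0 <= frac <= 1):
            raise ValueError(f"fraction for {rule} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    X = ds.counts.dense().copy()
    genes = ds.counts.genes
    mito_idx = np.array([i for i, g in enumerate(genes) if g.startswith("mt-")], dtype=int)
    stress_idx = np.array([i for i, g in enumerate(genes) if g.startswith("stress-")], dtype=int)
    special = set(mito_idx) | set(stress_idx)
    regular_idx = np.array([i for i in range(len(genes)) if i not in special], dtype=int)

    n_cells = X.shape[1]
    order = rng.permutation(n_cells)
    violations: Dict[str, List[str]] = {}
    pos = 0
    for rule in QC_RULES:
        frac = fractions.get(rule, 0.0)
        n_rule = int(round(frac * n_cells))
        chosen = order[pos:pos + n_rule]
        pos += n_rule
        for c in chosen:
            col = X[:, c]
            if rule == "low_complexity":
                col[:] = 0
                keep = rng.choice(regular_idx, size=150, replace=False)
                col[keep] = 1 + rng.poisson(1.0, size=150)
            elif rule == "high_complexity":
                total = max(int(col.sum()), 1)
                col *= math.ceil(16500 / total)
            else:  # high_mito / high_stress
                idx = mito_idx if rule == "high_mito" else stress_idx
                rest = int(col.sum()) - int(col[idx].sum())
                target = math.ceil(0.08 / (1 - 0.08) * max(rest, 1))
                col[idx] = rng.multinomial(target, np.full(idx.size, 1.0 / idx.size))
            violations.setdefault(ds.counts.cells[c], []).append(rule)

    counts = CountMatrix(sp.csr_matrix(X), genes.copy(), ds.counts.cells.copy())
    return LabeledDataset(
        counts=counts, cell_type=ds.cell_type.copy(),
        true_markers=dict(ds.true_markers),
        true_exclusive=dict(ds.true_exclusive),
        true_pseudotime=None if ds.true_pseudotime is None else ds.true_pseudotime.copy(),
        true_module=dict(ds.true_module), true_regulons=dict(ds.true_regulons),
        true_pathway_shift=dict(ds.true_pathway_shift), qc_violations=violations)


def generate_trajectory(config: GeneratorConfig, seed: Optional[int] = None) -> LabeledDataset:
    """A differentiation continuum: module genes follow temporal templates.

    Each module gene's NB mean is multiplied by ``marker_fold ** s(t)``
    where ``s`` is the module's template evaluated at the cell's true
    pseudotime (uniform on [0, 1]); non-module genes are flat.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tcfg = config.trajectory
    n_modules = int(tcfg["n_modules"])
    if n_modules < 2:
        raise ValueError("n_modules must be >= 2")
    templates = list(tcfg["templates"])
    if len(templates) != n_modules:
        raise ValueError("one template per module required")
    for name in templates:
        if name not in TRAJECTORY_TEMPLATES:
            raise ValueError(
                f"unknown template {name!r}; choose from {sorted(TRAJECTORY_TEMPLATES)}")

    regular, mito, stress = _gene_names(config)
    n_reg = len(regular)
    n_cells = int(tcfg["n_cells"])
    gpm = int(tcfg["genes_per_module"])
    base = _base_means(rng, n_reg, config.base_mean)
    module_idx = rng.choice(n_reg, size=n_modules * gpm, replace=False)
    base[module_idx] = config.base_mean * rng.uniform(0.5, 1.5, size=module_idx.size)
    module_by = module_idx.reshape(n_modules, gpm)

    t = rng.uniform(0.0, 1.0, size=n_cells)
    cellwise = np.ones((n_reg, n_cells))
    log_fold = math.log(config.marker_fold)
    for m, tmpl in enumerate(templates):
        shape = TRAJECTORY_TEMPLATES[tmpl](t)
        cellwise[module_by[m], :] = np.exp(log_fold * shape)[None, :]

    s = _Structure(names=np.concatenate([regular, mito, stress]), n_reg=n_reg,
                   base=base, marker_by_type=np.empty((1, 0), dtype=int),
                   exclusive_by_type=np.empty((1, 0), dtype=int),
                   type_names=["traj"], per_type=[n_cells])
    counts, cell_type = _draw_counts(config, s, rng, cellwise_mult=cellwise)
    true_module = {regular[g]: f"phase_{m + 1}"
                   for m in range(n_modules) for g in module_by[m]}
    return LabeledDataset(counts=counts, cell_type=cell_type,
                          true_module=true_module, true_pseudotime=t)


def generate_regulon_data(config: GeneratorConfig, seed: Optional[int] = None) -> LabeledDataset:
    """Cell-type programs plus TF-driven co-expression regulons.

    Within a TF's active type, the TF and its targets share an elevated
    latent factor, inducing positive pairwise correlation; elsewhere
    they sit at baseline.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rcfg = config.regulons
    n_tfs = int(rcfg["n_tfs"])
    targets_per = int(rcfg["targets_per_tf"])
    coupling = float(rcfg["coupling_strength"])

    s = _celltype_structure(config, rng)
    cell_type = np.repeat(s.type_names, s.per_type)
    n_cells = len(cell_type)
    active = rcfg.get("active_type_per_tf") or [
        s.type_names[i % len(s.type_names)] for i in range(n_tfs)]
    if len(active) != n_tfs:
        raise ValueError("active_type_per_tf must list one type per TF")
    for a in active:
        if a not in s.type_names:
            raise ValueError(f"unknown active type {a!r}")

    marker_flat = set(s.marker_by_type.ravel().tolist()) | set(s.exclusive_by_type.ravel().tolist())
    free = np.array([i for i in range(s.n_reg) if i not in marker_flat])
    need = n_tfs * (1 + targets_per)
    picked = free[rng.choice(free.size, size=need, replace=False)]
    picked = picked.reshape(n_tfs, 1 + targets_per)
    # regulon members get a dependable baseline, like markers
    s.base[picked.ravel()] = config.base_mean * rng.uniform(0.8, 1.2, size=picked.size)

    cellwise = np.ones((s.n_reg, n_cells))
    true_regulons = {}
    names = s.names
    for k in range(n_tfs):
        members = picked[k]
        in_type = np.flatnonzero(cell_type == active[k])
        if coupling > 0 and in_type.size:
            # a wide latent factor: the shared signal must dominate NB noise
            # for within-type TF-target correlation to be recoverable
            z = rng.lognormal(0.0, 1.0, size=in_type.size)
            mult = 1.0 + coupling * (config.marker_fold - 1.0) * z
            cellwise[np.ix_(members, in_type)] = mult[None, :]
        tf_name = f"tf_{k + 1:02d}"
        names[members[0]] = tf_name
        true_regulons[tf_name] = {
            "targets": [names[g] for g in members[1:]], "active_type": active[k]}

    counts, cell_type = _draw_counts(config, s, rng, cellwise_mult=cellwise,
                                     low_noise_genes=picked.ravel())
    true_markers = {names[g]: s.type_names[t]
                    for t in range(config.n_types) for g in s.marker_by_type[t]}
    true_exclusive = {names[g]: s.type_names[t]
                      for t in range(config.n_types) for g in s.exclusive_by_type[t]}
    true_markers.update(true_exclusive)
    return LabeledDataset(counts=counts, cell_type=cell_type,
                          true_markers=true_markers, true_exclusive=true_exclusive,
                          true_regulons=true_regulons)


def generate_timepoint_pair(config: GeneratorConfig,
                            seed: Optional[int] = None
                            ) -> Tuple[LabeledDataset, LabeledDataset]:
    """Two datasets sharing one expression structure; the second shifts
    ``up_frac`` of each pathway's genes up and ``down_frac`` down by
    ``shift_logfc`` (natural log), mimicking an earlier/later stage pair."""
    config.validate()
    pcfg = config.pathways
    shift = float(pcfg["shift_logfc"])
    if shift <= 0:
        raise ValueError("shift_logfc must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    s = _celltype_structure(config, rng)
    marker_flat = set(s.marker_by_type.ravel().tolist()) | set(s.exclusive_by_type.ravel().tolist())
    free = np.array([i for i in range(s.n_reg) if i not in marker_flat])
    names_list = list(pcfg["names"])
    gpp = int(pcfg["genes_per_pathway"])
    picked = free[rng.choice(free.size, size=len(names_list) * gpp, replace=False)]
    picked = picked.reshape(len(names_list), gpp)
    s.base[picked.ravel()] = config.base_mean * rng.uniform(0.5, 1.5, size=picked.size)

    up_frac = np.broadcast_to(np.asarray(pcfg["up_frac"], dtype=float), len(names_list))
    down_frac = np.broadcast_to(np.asarray(pcfg["down_frac"], dtype=float), len(names_list))
    log_mult = np.zeros(s.n_reg)
    shift_truth = {}
    for p, pname in enumerate(names_list):
        members = picked[p]
        n_up = int(round(up_frac[p] * gpp))
        n_down = int(round(down_frac[p] * gpp))
        up_genes, down_genes = members[:n_up], members[n_up:n_up + n_down]
        log_mult[up_genes] = shift
        log_mult[down_genes] = -shift
        direction = "up" if n_up > n_down else ("down" if n_down > n_up else "balanced")
        shift_truth[pname] = {
            "n_up": n_up, "n_down": n_down, "direction": direction,
            "genes": [s.names[g] for g in members],
            "up_genes": [s.names[g] for g in up_genes],
            "down_genes": [s.names[g] for g in down_genes]}

    true_markers = {s.names[g]: s.type_names[t]
                    for t in range(config.n_types) for g in s.marker_by_type[t]}
    counts1, cell_type1 = _draw_counts(config, s, rng, cell_prefix="t1cell")
    counts2, cell_type2 = _draw_counts(config, s, rng, gene_log_mult=log_mult,
                                       cell_prefix="t2cell")
    mk = lambda cm, ct: LabeledDataset(counts=cm, cell_type=ct,
                                       true_markers=true_markers,
                                       true_pathway_shift=shift_truth)
    return mk(counts1, cell_type1), mk(counts2, cell_type2)
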