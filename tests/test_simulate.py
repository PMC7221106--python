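import numpy as np
import pytest

from cochleasc import simulate as sim
from cochleasc.config import GeneratorConfig

from conftest import small_generator_config


class TestCelltypeGenerator:
    def test_seed_determinism(self):
        cfg = small_generator_config()
        a = sim.generate_celltypes(cfg, seed=5)
        b = sim.generate_celltypes(cfg, seed=5)
        assert (a.counts.X != b.counts.X).nnz == 0
        assert list(a.cell_type) == list(b.cell_type)
        assert a.true_markers == b.true_markers

    def test_marker_fold_one_separates_nothing(self):
        cfg = small_generator_config(marker_fold=1.0 + 1e-9)
        ds = sim.generate_celltypes(cfg, seed=2)
        X = ds.counts.dense()
        lfcs = []
        for g, t in list(ds.true_markers.items())[:30]:
            if g in ds.true_exclusive:
                continue
            gi = int(np.flatnonzero(ds.counts.genes == g)[0])
            in_t = ds.cell_type == t
            lfcs.append(np.log((X[gi, in_t].mean() + 0.1) / (X[gi, ~in_t].mean() + 0.1)))
        assert abs(np.mean(lfcs)) < 0.1

    def test_empirical_marker_fold_matches_configured(self):
        # Monte-Carlo self-consistency: configured 8-fold recovered within 25%
        cfg = small_generator_config(n_types=2, n_cells_per_type=200,
                                     markers_per_type=10, marker_fold=8.0)
        ratios = []
        for seed in range(10):
            ds = sim.generate_celltypes(cfg, seed=seed)
            X = ds.counts.dense()
            for g, t in ds.true_markers.items():
                if g in ds.true_exclusive:
                    continue
                gi = int(np.flatnonzero(ds.counts.genes == g)[0])
                in_t = ds.cell_type == t
                ratios.append(X[gi, in_t].mean() / max(X[gi, ~in_t].mean(), 1e-9))
        assert abs(np.median(ratios) - 8.0) / 8.0 < 0.25

    def test_planted_roles_disjoint(self):
        ds = sim.generate_regulon_data(small_generator_config(), seed=1)
        markers = set(ds.true_markers)
        reg_genes = {g for info in ds.true_regulons.values()
                     for g in [*info["targets"]]} | set(ds.true_regulons)
        assert not markers & reg_genes

    def test_exclusive_genes_off_elsewhere(self, small_dataset):
        ds = small_dataset
        X = ds.counts.dense()
        for g, t in list(ds.true_exclusive.items())[:10]:
            gi = int(np.flatnonzero(ds.counts.genes == g)[0])
            off = X[gi, ds.cell_type != t]
            assert (off > 0).mean() < 0.08  # well under the 0.1 screen bound


class TestQCOutliers:
    def test_exact_fraction_of_low_complexity_cells(self):
        cfg = small_generator_config(n_types=2, n_cells_per_type=50)
        ds = sim.generate_celltypes(cfg, seed=7)
        out = sim.inject_qc_outliers(ds, {"low_complexity": 0.1}, seed=1)
        detected = out.counts.detected_genes_per_cell()
        n_low = int((detected < 200).sum())
        assert n_low == 10
        assert len(out.qc_violations) == 10

    def test_zero_fractions_leave_dataset_unchanged(self, small_dataset):
        out = sim.inject_qc_outliers(small_dataset, {}, seed=1)
        assert (out.counts.X != small_dataset.counts.X).nnz == 0
        assert out.qc_violations == {}

    def test_high_mito_cells_exceed_share_bound(self, small_dataset):
        out = sim.inject_qc_outliers(small_dataset, {"high_mito": 0.05}, seed=2)
        X = out.counts.dense()
        mito = np.array([g.startswith("mt-") for g in out.counts.genes])
        for cell, rules in out.qc_violations.items():
            assert rules == ["high_mito"]
            c = int(np.flatnonzero(out.counts.cells == cell)[0])
            assert X[mito, c].sum() / X[:, c].sum() > 0.05

    def test_unknown_rule_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="unknown QC rule"):
            sim.inject_qc_outliers(small_dataset, {"weird": 0.1}, seed=0)


class TestTrajectoryGenerator:
    def test_early_decreasing_spans_the_full_fold(self):
        f = sim.TRAJECTORY_TEMPLATES["early_decreasing"]
        fold = 6.0
        assert fold ** f(0.0) / fold ** f(1.0) >= fold

    def test_preset_plants_four_modules(self):
        ds = sim.generate_trajectory(small_generator_config(), seed=3)
        assert len(set(ds.true_module.values())) == 4
        assert ds.true_pseudotime.min() >= 0 and ds.true_pseudotime.max() <= 1

    def test_transient_peak_gene_has_interior_maximum(self):
        cfg = small_generator_config()
        ds = sim.generate_trajectory(cfg, seed=4)
        t = ds.true_pseudotime
        X = ds.counts.dense()
        order = np.argsort(t)
        peak_genes = [g for g, m in ds.true_module.items() if m == "phase_2"][:5]
        for g in peak_genes:
            gi = int(np.flatnonzero(ds.counts.genes == g)[0])
            y = X[gi, order].astype(float)
            smooth = np.convolve(y, np.ones(80) / 80, mode="valid")
            am = np.argmax(smooth)
            assert 0.1 * len(smooth) < am < 0.9 * len(smooth)

    def test_unknown_template_rejected(self):
        cfg = small_generator_config()
        cfg.trajectory = dict(cfg.trajectory)
        cfg.trajectory["templates"] = ["early_decreasing", "nope", "mid_rising",
                                       "late_rising"]
        with pytest.raises(ValueError, match="unknown template"):
            sim.generate_trajectory(cfg, seed=0)


class TestRegulonGenerator:
    def test_zero_coupling_gives_no_correlation(self):
        # on depth-normalized expression (library-size confounding removed)
        from cochleasc import qc
        cfg = small_generator_config()
        cfg.regulons = dict(cfg.regulons, n_tfs=3, targets_per_tf=10,
                            coupling_strength=0.0)
        ds = sim.generate_regulon_data(cfg, seed=5)
        X = qc.normalize_log(ds.counts).dense()
        names = {g: i for i, g in enumerate(ds.counts.genes)}
        cors = []
        for tf, info in ds.true_regulons.items():
            in_t = ds.cell_type == info["active_type"]
            for tgt in info["targets"][:5]:
                cors.append(np.corrcoef(X[names[tf], in_t], X[names[tgt], in_t])[0, 1])
        assert abs(np.median(cors)) < 0.15

    def test_strong_coupling_correlates_tf_and_targets(self):
        cfg = small_generator_config(n_cells_per_type=100)
        cfg.regulons = dict(cfg.regulons, n_tfs=3, targets_per_tf=10,
                            coupling_strength=0.8)
        hits = total = 0
        for seed in range(5):
            ds = sim.generate_regulon_data(cfg, seed=seed)
            X = ds.counts.dense().astype(float)
            names = {g: i for i, g in enumerate(ds.counts.genes)}
            for tf, info in ds.true_regulons.items():
                in_t = ds.cell_type == info["active_type"]
                for tgt in info["targets"]:
                    c = np.corrcoef(X[names[tf], in_t], X[names[tgt], in_t])[0, 1]
                    hits += c > 0.5
                    total += 1
        assert hits / total >= 0.9

    def test_targets_of_distinct_tfs_disjoint(self):
        ds = sim.generate_regulon_data(small_generator_config(), seed=6)
        seen = set()
        for info in ds.true_regulons.values():
            tgt = set(info["targets"])
            assert not tgt & seen
            seen |= tgt


class TestTimepointPair:
    def test_recorded_truth_matches_fractions(self):
        cfg = small_generator_config()
        cfg.pathways = dict(cfg.pathways, names=["pw"], genes_per_pathway=4,
                            up_frac=0.75, down_frac=0.25)
        _, ds2 = sim.generate_timepoint_pair(cfg, seed=1)
        truth = ds2.true_pathway_shift["pw"]
        assert (truth["n_up"], truth["n_down"]) == (3, 1)
        assert truth["direction"] == "up"

    def test_no_shift_gives_exchangeable_draws(self):
        cfg = small_generator_config()
        cfg.pathways = dict(cfg.pathways, up_frac=0.0, down_frac=0.0)
        ds1, ds2 = sim.generate_timepoint_pair(cfg, seed=2)
        m1 = np.asarray(ds1.counts.X.mean(axis=1)).ravel()
        m2 = np.asarray(ds2.counts.X.mean(axis=1)).ravel()
        # same expression program: per-gene means agree closely
        big = m1 > 1
        assert np.median(np.abs(np.log((m2[big] + 0.1) / (m1[big] + 0.1)))) < 0.15

    def test_nonpositive_shift_rejected(self):
        cfg = small_generator_config()
        cfg.pathways = dict(cfg.pathways, shift_logfc=-0.5)
        with pytest.raises(ValueError):
            sim.generate_timepoint_pair(cfg, seed=0)
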