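import numpy as np
import pandas as pd
import pytest

from cochleasc import markers as mk, qc

from conftest import expr_from_dense


def nb_counts(rng, mean, r, size):
    return rng.negative_binomial(r, r / (r + mean), size=size)


class TestDeTwoGroups:
    def _null_expr(self, seed=0, n_genes=40, n=30):
        rng = np.random.default_rng(seed)
        X = np.log1p(nb_counts(rng, 5.0, 2.0, (n_genes, 2 * n)).astype(float))
        return expr_from_dense(X), np.arange(n), np.arange(n, 2 * n)

    def test_group_exchange_negates_lfc_and_keeps_p(self):
        expr, a, b = self._null_expr(seed=1)
        r1 = mk.de_two_groups(expr, a, b, min_pct=0, logfc_threshold=0)
        r2 = mk.de_two_groups(expr, b, a, min_pct=0, logfc_threshold=0)
        m1 = r1.set_index("gene")
        m2 = r2.set_index("gene")
        common = m1.index.intersection(m2.index)
        assert np.allclose(m1.loc[common, "avg_logfc"],
                           -m2.loc[common, "avg_logfc"])
        assert np.allclose(m1.loc[common, "p_value"], m2.loc[common, "p_value"])

    def test_identical_distributions_filtered_by_lfc_gate(self):
        expr, a, b = self._null_expr(seed=2, n_genes=40, n=100)
        rec = mk.de_two_groups(expr, a, b, min_pct=0.25, logfc_threshold=0.25)
        # null genes rarely clear a 0.25 natural-log fold gate
        assert len(rec) <= 2

    def test_min_pct_gate_excludes_rarely_detected_genes(self):
        X = np.zeros((1, 40))
        X[0, :2] = 1.0   # 10% of A
        X[0, 20] = 1.0   # 5% of B
        expr = expr_from_dense(X)
        rec = mk.de_two_groups(expr, np.arange(20), np.arange(20, 40),
                               min_pct=0.25, logfc_threshold=0.0)
        assert rec.empty

    def test_bonferroni_is_p_times_n_tested(self):
        expr, a, b = self._null_expr(seed=3)
        rec = mk.de_two_groups(expr, a, b, min_pct=0, logfc_threshold=0)
        n = len(rec)
        assert np.allclose(rec["adj_p"], np.minimum(1.0, rec["p_value"] * n))

    def test_power_on_twofold_shift(self):
        # 100 replicate genes, each 2-fold shifted, n=100 per group
        rng = np.random.default_rng(4)
        A = nb_counts(rng, 20.0, 2.0, (100, 100))
        B = nb_counts(rng, 10.0, 2.0, (100, 100))
        expr = expr_from_dense(np.log1p(np.hstack([A, B]).astype(float)))
        rec = mk.de_two_groups(expr, np.arange(100), np.arange(100, 200),
                               min_pct=0, logfc_threshold=0)
        frac = (rec["adj_p"] < 0.01).mean() * len(rec) / 100
        assert frac >= 0.95

    def test_small_group_rejected(self):
        expr, a, b = self._null_expr()
        with pytest.raises(ValueError, match="at least 3"):
            mk.de_two_groups(expr, a[:2], b)

    def test_type_i_error_at_nominal_level(self):
        # null NB data, alpha=0.05: empirical rate within binomial CI
        rng = np.random.default_rng(5)
        X = np.log1p(nb_counts(rng, 6.0, 2.0, (1000, 120)).astype(float))
        expr = expr_from_dense(X)
        rec = mk.de_two_groups(expr, np.arange(60), np.arange(60, 120),
                               min_pct=0, logfc_threshold=0)
        rate = (rec["p_value"] < 0.05).sum() / 1000
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 1000)


class TestFindAllAndTop:
    def test_planted_marker_recovery(self, small_dataset, small_expr):
        expr, counts = small_expr
        rec = mk.find_all_markers(expr, small_dataset.cell_type, only_positive=True)
        sig = rec[rec["adj_p"] < 0.05]
        found = set(zip(sig["gene"], sig["cluster"]))
        planted = [(g, t) for g, t in small_dataset.true_markers.items()
                   if g in set(counts.genes)]
        hit = sum(1 for gt in planted if gt in found)
        assert hit / len(planted) >= 0.9

    def test_exclusive_marker_has_low_pct_out(self, small_dataset, small_expr):
        expr, counts = small_expr
        rec = mk.find_all_markers(expr, small_dataset.cell_type, only_positive=True)
        gene_set = set(counts.genes)
        excl = [(g, t) for g, t in small_dataset.true_exclusive.items() if g in gene_set]
        sub = rec.set_index(["gene", "cluster"])
        checked = 0
        for g, t in excl:
            if (g, t) in sub.index:
                assert sub.loc[(g, t), "pct_out"] < 0.1
                checked += 1
        assert checked >= len(excl) * 0.9

    def test_top_markers_shape_order_and_ties(self):
        rec = pd.DataFrame({
            "gene": ["g1", "g2", "g3", "g4", "g5"],
            "cluster": ["A", "A", "A", "B", "B"],
            "avg_logfc": [1.0, 2.0, 1.0, -0.5, 0.3],
            "adj_p": [0.01, 0.02, 0.01, 0.001, 0.04],
        })
        top = mk.top_markers(rec, n=25)
        # negative record dropped; A ordered by lfc desc then adj_p then name
        assert list(top["gene"]) == ["g2", "g1", "g3", "g5"]
        top2 = mk.top_markers(rec, n=1)
        assert list(top2["gene"]) == ["g2", "g5"]


class TestExclusiveScreen:
    def test_hand_fixture_inclusion_rules(self):
        # gene0: 90% in target, 2% elsewhere -> in; gene1: 60% in two clusters -> out
        X = np.zeros((2, 100))
        X[0, :45] = 1.0   # 90% of target (cells 0..49)
        X[0, 50] = 1.0    # 2% of others
        X[1, :30] = 1.0   # 60% of target
        X[1, 50:80] = 1.0  # 60% of other
        expr = expr_from_dense(X)
        labels = np.repeat(["t", "o"], 50)
        got = mk.exclusive_genes(expr, labels, "t", f_on=0.3, f_off=0.1)
        assert got == ["g0"]

    def test_recovery_on_generator(self, small_dataset, small_expr):
        expr, counts = small_expr
        gene_set = set(counts.genes)
        precs, recs = [], []
        for t in ["type_01", "type_04"]:
            truth = {g for g, tt in small_dataset.true_exclusive.items()
                     if tt == t and g in gene_set}
            got = set(mk.exclusive_genes(expr, small_dataset.cell_type, t, 0.3, 0.1))
            precs.append(len(got & truth) / len(got) if got else 1.0)
            recs.append(len(got & truth) / len(truth))
        assert min(precs) >= 0.9 and min(recs) >= 0.9

    def test_missing_cluster_rejected(self, small_expr):
        expr, _ = small_expr
        with pytest.raises(KeyError):
            mk.exclusive_genes(expr, ["a"] * expr.n_cells, "nope")


class TestZScoreMatrix:
    def test_hand_oracle_two_clusters(self):
        X = np.array([[1.0, 3.0, 5.0, 7.0]])
        expr = expr_from_dense(X)
        Z = mk.celltype_zscore_matrix(expr, ["a", "a", "b", "b"], ["g0"])
        z = (X[0] - 4.0) / np.std(X[0])
        assert Z.loc["g0", "a"] == pytest.approx(z[:2].mean())
        assert Z.loc["g0", "b"] == pytest.approx(z[2:].mean())

    def test_uniform_gene_gives_zero_row_with_warning(self):
        expr = expr_from_dense(np.full((1, 6), 2.0))
        with pytest.warns(UserWarning, match="zero-variance"):
            Z = mk.celltype_zscore_matrix(expr, ["a", "a", "a", "b", "b", "b"], ["g0"])
        assert (Z.values == 0).all()

    def test_restricted_gene_sign_pattern(self):
        X = np.zeros((1, 9))
        X[0, :3] = 5.0
        expr = expr_from_dense(X)
        Z = mk.celltype_zscore_matrix(expr, list("aaabbbccc"), ["g0"])
        assert Z.loc["g0", "a"] > 0 > Z.loc["g0", "b"]
        assert Z.loc["g0", "c"] < 0


class TestConcordance:
    def _records(self, genes, lfcs):
        return pd.DataFrame({"gene": genes, "cluster": "A",
                             "avg_logfc": lfcs, "pct_in": 0.5, "pct_out": 0.1,
                             "p_value": 0.001, "adj_p": 0.01})

    def test_direct_count_oracle(self):
        # 10 genes, reference fold >= 2 for all, 8 direction matches
        genes = [f"g{i}" for i in range(10)]
        lfcs = [1.0] * 8 + [-1.0] * 2
        ref_a = {g: 8.0 for g in genes}
        ref_b = {g: 2.0 for g in genes}   # fold (8+1)/(2+1) = 3, direction up
        res = mk.cross_dataset_concordance(self._records(genes, lfcs), ref_a, ref_b, 2.0)
        assert (res.n_eligible, res.n_concordant) == (10, 8)
        assert res.fraction == pytest.approx(0.8)

    def test_subthreshold_fold_not_eligible(self):
        res = mk.cross_dataset_concordance(
            self._records(["g0"], [1.0]), {"g0": 2.0}, {"g0": 1.0}, 2.0)
        assert res.n_eligible == 0  # fold (2+1)/(1+1)=1.5 < 2

    def test_missing_reference_gene_counted_separately(self):
        res = mk.cross_dataset_concordance(
            self._records(["g0", "gX"], [1.0, 1.0]),
            {"g0": 9.0}, {"g0": 1.0}, 2.0)
        assert res.n_not_detected == 1
        assert res.n_eligible == 1
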