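import math

import numpy as np
import pandas as pd
import pytest

from cochleasc import qc, regulons as rg, simulate as sim
from cochleasc.containers import GeneMatrix

from conftest import small_generator_config


def js_divergence_oracle(p, q):
    """Direct summation Jensen-Shannon divergence in log base 2."""
    m = 0.5 * (np.asarray(p) + np.asarray(q))

    def kl(a, b):
        s = 0.0
        for ai, bi in zip(a, b):
            if ai > 0:
                s += ai * math.log2(ai / bi)
        return s

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def ras_oracle(expr_col, gene_names, targets, top_fraction):
    """Brute-force recovery-curve AUC by direct enumeration of the step curve."""
    order = sorted(range(len(gene_names)),
                   key=lambda i: (-expr_col[i], str(gene_names[i])))
    m = math.ceil(top_fraction * len(gene_names))
    target_set = set(targets)
    hits = 0
    area = 0
    for x in range(m):
        if gene_names[order[x]] in target_set:
            hits += 1
        area += hits
    max_area = sum(min(x, len(targets)) for x in range(1, m + 1))
    return area / max_area


class TestPseudocells:
    def test_member_counts_within_bounds(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(3.0, size=(30, 200)).astype(float)
        gm = GeneMatrix(X, [f"g{i}" for i in range(30)], [f"c{j}" for j in range(200)])
        labels = np.repeat(["a", "b"], 100)
        pc = rg.make_pseudocells(gm, labels, pool_min=5, pool_max=20, n_per_type=30,
                                 seed=1)
        assert pc.n_pseudocells == 60
        assert pc.member_count.min() >= 5 and pc.member_count.max() <= 20

    def test_pooling_identical_cells_is_identity(self):
        prof = np.array([1.0, 2.0, 3.0])
        X = np.tile(prof[:, None], (1, 20))
        gm = GeneMatrix(X, ["g0", "g1", "g2"], [f"c{j}" for j in range(20)])
        pc = rg.make_pseudocells(gm, ["t"] * 20, n_per_type=5, seed=0)
        assert np.allclose(pc.X, prof[:, None])

    def test_small_type_skipped_with_warning(self):
        X = np.ones((3, 14))
        gm = GeneMatrix(X, list("abc"), [f"c{j}" for j in range(14)])
        labels = ["big"] * 10 + ["tiny"] * 4
        with pytest.warns(UserWarning, match="tiny"):
            pc = rg.make_pseudocells(gm, labels, pool_min=5, n_per_type=3, seed=0)
        assert set(pc.cell_type) == {"big"}

    def test_invalid_arguments_rejected(self):
        gm = GeneMatrix(np.ones((2, 10)), ["a", "b"], [f"c{j}" for j in range(10)])
        with pytest.raises(ValueError):
            rg.make_pseudocells(gm, ["t"] * 10, n_per_type=0)
        with pytest.raises(ValueError):
            rg.make_pseudocells(gm, ["t"] * 10, pool_min=8, pool_max=5)


class TestInferRegulons:
    def test_planted_regulons_recovered(self):
        gcfg = small_generator_config(n_cells_per_type=100)
        gcfg.regulons = dict(gcfg.regulons, n_tfs=3, targets_per_tf=10,
                             coupling_strength=0.8)
        ds = sim.generate_regulon_data(gcfg, seed=2)
        counts = qc.filter_genes(ds.counts, 10)
        expr = qc.normalize_log(counts)
        pc = rg.make_pseudocells(expr, ds.cell_type, n_per_type=40, seed=0)
        regs = rg.infer_regulons(pc, list(ds.true_regulons), corr_threshold=0.3)
        assert len(regs) == 3
        for r in regs:
            truth = set(ds.true_regulons[r.tf]["targets"])
            assert len(set(r.targets) & truth) / len(truth) >= 0.8

    def test_uncorrelated_tf_dropped_and_cap_respected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 50))
        X[1] = X[0] + 0.1 * rng.normal(size=50)
        X[2] = X[0] + 0.1 * rng.normal(size=50)
        gm = rg.PseudocellMatrix(X, np.array([f"g{i}" for i in range(20)], dtype=object),
                                 np.array(["t"] * 50, dtype=object), np.full(50, 5))
        regs = rg.infer_regulons(gm, ["g0", "g19"], corr_threshold=0.6, max_targets=1)
        assert [r.tf for r in regs] == ["g0"]
        assert len(regs[0].targets) == 1

    def test_tf_never_its_own_target(self):
        with pytest.raises(ValueError):
            rg.Regulon(tf="a", targets=["a", "b"])


class TestRAS:
    def _pc(self, X, genes):
        return rg.PseudocellMatrix(np.asarray(X, dtype=float),
                                   np.array(genes, dtype=object),
                                   np.array(["t"] * np.asarray(X).shape[1], dtype=object),
                                   np.full(np.asarray(X).shape[1], 5))

    def test_targets_at_top_score_one_and_absent_score_zero(self):
        genes = [f"g{i}" for i in range(20)]
        X = np.arange(20, 0, -1, dtype=float)[:, None]  # g0 highest
        pc = self._pc(X, genes)
        top = rg.Regulon(tf="tf", targets=["g0", "g1"])
        bottom = rg.Regulon(tf="tf", targets=["g18", "g19"])
        assert rg.regulon_activity(pc, top, top_fraction=0.2)[0] == pytest.approx(1.0)
        assert rg.regulon_activity(pc, bottom, top_fraction=0.2)[0] == 0.0

    def test_matches_brute_force_enumeration_on_toys(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(10)]
        for trial in range(20):
            X = rng.integers(0, 6, size=(10, 1)).astype(float)
            targets = list(rng.choice(genes, size=3, replace=False))
            pc = self._pc(X, genes)
            got = rg.regulon_activity(pc, rg.Regulon(tf="tf", targets=targets),
                                      top_fraction=0.3)[0]
            want = ras_oracle(X[:, 0], genes, targets, 0.3)
            assert got == pytest.approx(want, abs=1e-12)

    def test_empty_regulon_rejected(self):
        pc = self._pc(np.ones((5, 2)), list("abcde"))
        with pytest.raises(ValueError):
            rg.regulon_activity(pc, rg.Regulon(tf="tf", targets=[]))


class TestRSS:
    def test_indicator_match_scores_one(self):
        ras = np.array([0.5, 0.5, 0.0, 0.0])
        types = np.array(["a", "a", "b", "b"])
        assert rg.regulon_specificity(ras, types, "a") == pytest.approx(1.0)

    def test_disjoint_support_scores_zero(self):
        ras = np.array([0.0, 0.0, 0.3, 0.7])
        types = np.array(["a", "a", "b", "b"])
        assert rg.regulon_specificity(ras, types, "a") == pytest.approx(0.0, abs=1e-12)

    def test_hand_summed_oracle_example(self):
        ras = np.array([0.4, 0.4, 0.1, 0.1])
        types = np.array(["a", "a", "b", "b"])
        jsd = js_divergence_oracle(ras / ras.sum(), [0.5, 0.5, 0.0, 0.0])
        want = 1.0 - math.sqrt(jsd)
        assert rg.regulon_specificity(ras, types, "a") == pytest.approx(want, abs=1e-12)

    def test_matches_direct_summation_on_random_distributions(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(4, 12))
            ras = rng.uniform(0, 1, n)
            ras[rng.integers(0, n)] = 0.0
            types = rng.choice(["a", "b", "c"], size=n)
            if not (types == "a").any():
                types[0] = "a"
            p = ras / ras.sum()
            q = (types == "a") / (types == "a").sum()
            want = 1.0 - math.sqrt(js_divergence_oracle(p, q))
            got = rg.regulon_specificity(ras, types, "a")
            assert got == pytest.approx(want, abs=1e-12)

    def test_specificity_decreases_as_mass_leaves_target_type(self):
        types = np.array(["a"] * 5 + ["b"] * 5)
        prev = np.inf
        for off in np.linspace(0, 0.8, 9):
            ras = np.concatenate([np.full(5, (1 - off) / 5), np.full(5, off / 5)])
            val = rg.regulon_specificity(ras, types, "a")
            assert val < prev
            prev = val

    def test_all_zero_ras_rejected(self):
        with pytest.raises(ValueError):
            rg.regulon_specificity(np.zeros(4), np.array(["a", "a", "b", "b"]), "a")


class TestRanking:
    def test_single_regulon_ranks_first_and_permutation_invariant(self):
        rss = pd.DataFrame({"a": [0.9]}, index=["tf1"])
        assert rg.rank_regulons(rss, "a").iloc[0]["rank"] == 1
        rss3 = pd.DataFrame({"a": [0.2, 0.9, 0.5]}, index=["t3", "t1", "t2"])
        order1 = list(rg.rank_regulons(rss3, "a")["regulon"])
        order2 = list(rg.rank_regulons(rss3.iloc[::-1], "a")["regulon"])
        assert order1 == order2 == ["t1", "t2", "t3"]

    def test_ties_break_by_name(self):
        rss = pd.DataFrame({"a": [0.5, 0.5]}, index=["zeta", "alpha"])
        assert list(rg.rank_regulons(rss, "a")["regulon"]) == ["alpha", "zeta"]
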