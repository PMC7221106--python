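import numpy as np
import pytest
import scipy.sparse as sp

from cochleasc.config import GeneratorConfig
from cochleasc.containers import CountMatrix, ExpressionMatrix
from cochleasc import qc, simulate as sim


def small_generator_config(**over) -> GeneratorConfig:
    """A fast, scaled-down generator: 6 types x 60 cells x 600 genes."""
    # base_mean raised so small cells clear the 1500-UMI QC floor comfortably
    base = dict(n_genes=600, n_types=6, n_cells_per_type=60, markers_per_type=12,
                exclusive_per_type=3, marker_fold=6.0, base_mean=8.0, seed=0)
    base.update(over)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return sim.generate_celltypes(small_generator_config(), seed=11)


@pytest.fixture(scope="session")
def small_expr(small_dataset):
    counts = qc.filter_genes(small_dataset.counts, 10)
    return qc.normalize_log(counts), counts


@pytest.fixture
def tiny_counts():
    """3 genes x 4 cells with hand-checkable values."""
    X = sp.csr_matrix(np.array([[5, 0, 2, 1],
                                [0, 3, 0, 4],
                                [1, 1, 1, 1]]))
    return CountMatrix(X, ["ga", "gb", "gc"], ["c1", "c2", "c3", "c4"])


def expr_from_dense(X, genes=None, cells=None) -> ExpressionMatrix:
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i}" for i in range(X.shape[0])]
    cells = cells or [f"c{j}" for j in range(X.shape[1])]
    return ExpressionMatrix(X, genes, cells)
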