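"""Readers and writers for the standard on-disk formats.

10x-style directories hold a MatrixMarket triplet file (``matrix.mtx``)
with genes as rows, plus ``genes.tsv`` and ``barcodes.tsv`` tables, one
identifier per line (a second tab-separated column, as in real 10x gene
tables, is tolerated and ignored). GMT gene-set files are tab-separated:
name, description, then member genes.
"""
from __future__ import annotations

import os
from typing import Dict, List

import numpy as np
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix

MATRIX_FILE = "matrix.mtx"
GENES_FILE = "genes.tsv"
BARCODES_FILE = "barcodes.tsv"


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


def _read_id_table(path: str) -> List[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_10x_mtx(dir_path: str) -> CountMatrix:
    """Read a 10x-style directory into a genes x cells :class:`CountMatrix`.

    Raises ``FileNotFoundError`` naming any missing file and
    :class:`FormatError` when table lengths disagree with the matrix header.
    """
    paths = {name: os.path.join(dir_path, name)
             for name in (MATRIX_FILE, GENES_FILE, BARCODES_FILE)}
    for name, p in paths.items():
        if not os.path.exists(p):
            raise FileNotFoundError(f"missing {name} in {dir_path}")
    X = scipy.io.mmread(paths[MATRIX_FILE]).tocsr()
    genes = _read_id_table(paths[GENES_FILE])
    cells = _read_id_table(paths[BARCODES_FILE])
    if X.shape[0] != len(genes):
        raise FormatError(
            f"{GENES_FILE}: expected {X.shape[0]} genes from matrix header, found {len(genes)}")
    if X.shape[1] != len(cells):
        raise FormatError(
            f"{BARCODES_FILE}: expected {X.shape[1]} barcodes from matrix header, found {len(cells)}")
    data = X.data
    if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
        raise FormatError(f"{MATRIX_FILE}: counts must be nonnegative integers")
    return CountMatrix(X.astype(np.int64), np.array(genes, dtype=object),
                       np.array(cells, dtype=object))


def write_10x_mtx(cm: CountMatrix, dir_path: str) -> None:
    """Write a :class:`CountMatrix` as matrix.mtx + genes.tsv + barcodes.tsv."""
    os.makedirs(dir_path, exist_ok=True)
    X = cm.X if sp.issparse(cm.X) else sp.csr_matrix(cm.X)
    scipy.io.mmwrite(os.path.join(dir_path, MATRIX_FILE), X.tocoo(), field="integer")
    for fname, ids in ((GENES_FILE, cm.genes), (BARCODES_FILE, cm.cells)):
        with open(os.path.join(dir_path, fname), "w") as fh:
            fh.writelines(f"{i}\n" for i in ids)


def read_gmt(path: str) -> Dict[str, List[str]]:
    """Read a GMT file into ``{set name: unique member gene list}``.

    Duplicate members within one set are kept once (first occurrence);
    a line with fewer than three fields raises :class:`FormatError`
    with its line number.
    """
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, _desc, *members = fields
            seen: Dict[str, None] = {}
            for m in members:
                if m and m not in seen:
                    seen[m] = None
            sets[name] = list(seen)
    return sets


def write_gmt(sets: Dict[str, List[str]], path: str, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
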