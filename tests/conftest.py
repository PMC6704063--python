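import numpy as np
import pandas as pd
import pytest

from scmetab import CellAnnotation, ExpressionMatrix, GeneSetCollection


def make_matrix(values, genes=None, cells=None, unit="log2tpm1"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cells), unit)


def make_annotation(cells, cell_types, tumors=None, malignant=None):
    n = len(cells)
    return CellAnnotation(pd.DataFrame({
        "tumor_id": tumors or ["t1"] * n,
        "cell_type": cell_types,
        "malignant": malignant if malignant is not None else [False] * n,
    }, index=pd.Index(cells, name="cell_id")))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix():
    return make_matrix([[1.0, 3.0, 2.0, 4.0],
                        [0.0, 0.0, 1.0, 2.0],
                        [5.0, 5.0, 5.0, 5.0]],
                       genes=["G0", "G1", "G2"], cells=["c0", "c1", "c2", "c3"])


@pytest.fixture
def small_annotation(small_matrix):
    return make_annotation(list(small_matrix.cell_ids),
                           ["A", "A", "B", "B"],
                           tumors=["t1", "t1", "t2", "t2"])


@pytest.fixture
def two_sets():
    return GeneSetCollection({"S1": ["G0", "G1"], "S2": ["G1", "G2"]})
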