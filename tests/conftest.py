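import numpy as np
import pandas as pd
import pytest

from gsc import ExpressionMatrix, GeneSet


def make_matrix(values, organism="test_org", prefix="g"):
    """ExpressionMatrix from a nested list / ndarray of per-gene rows."""
    values = np.asarray(values, dtype=float)
    genes = [f"{prefix}{i}" for i in range(values.shape[0])]
    arrays = [f"a{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        organism=organism,
        data=pd.DataFrame(values, index=genes, columns=arrays),
    )


def make_set(matrix, gene_ids=None, set_id="S", source="SRC"):
    genes = gene_ids if gene_ids is not None else matrix.gene_ids
    return GeneSet(set_id=set_id, genes=frozenset(genes), source=source)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_matrix(rng):
    """A 6-gene x 8-array matrix of plausible log2 values."""
    return make_matrix(rng.normal(7.0, 1.5, size=(6, 8)))
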