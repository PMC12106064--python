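import numpy as np
import pytest

from taxaudit import (
    EmbeddingMatrix,
    SimilarityMatrix,
    generate_taxonomy,
)

POOL_CSV = """inventory_id,scale_id,item_id,text,key,label
inv1,sA,i1,enjoy tidy rooms,1,orderliness
inv1,sA,i2,keep things in order,1,orderliness
inv1,sB,i3,talk to strangers,1,sociability
inv1,sB,i4,love big parties,-1,sociability
"""


@pytest.fixture
def pool_csv(tmp_path):
    path = tmp_path / "pool.csv"
    path.write_text(POOL_CSV)
    return path


@pytest.fixture(scope="session")
def planted6():
    """Zero-noise planted taxonomy: 6 constructs x 3 scales x 8 items."""
    return generate_taxonomy(K=6, m=3, p=8, dim=64, seed=11)


def sim_from_values(ids, values, calibrated=False):
    """Square SimilarityMatrix from a dense array."""
    return SimilarityMatrix(tuple(ids), tuple(ids), np.asarray(values, float),
                            calibrated=calibrated)


def sim_from_pairs(ids, pairs, diag=1.0):
    """Square symmetric SimilarityMatrix from {(a, b): value} pairs."""
    n = len(ids)
    idx = {x: i for i, x in enumerate(ids)}
    V = np.full((n, n), np.nan)
    np.fill_diagonal(V, diag)
    for (a, b), v in pairs.items():
        V[idx[a], idx[b]] = v
        V[idx[b], idx[a]] = v
    if np.isnan(V).any():
        raise AssertionError("incomplete pair specification")
    return SimilarityMatrix(tuple(ids), tuple(ids), V)


@pytest.fixture
def emb():
    def make(ids, rows):
        return EmbeddingMatrix(tuple(ids), np.asarray(rows, float))

    return make
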