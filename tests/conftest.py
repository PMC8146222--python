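import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def small_matrix() -> pd.DataFrame:
    """3 genes x 2 samples, hand-written FPKM values."""
    return pd.DataFrame(
        [[1.0, 2.0], [0.0, 0.5], [10.0, 0.1]],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=["s1", "s2"],
    )


@pytest.fixture
def mixed_annotation() -> pd.DataFrame:
    """4 genes: 2 mRNA, 1 lncRNA, 1 other."""
    return pd.DataFrame(
        {
            "symbol": ["A", "B", "C", "D"],
            "biotype": ["mRNA", "mRNA", "lncRNA", "other"],
            "chromosome": ["chr1", "chr2", "chr1", "chrX"],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_adjacency(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random symmetric adjacency in [0, 1] with unit diagonal."""
    a = rng.random((n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    idx = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
    return pd.DataFrame(a, index=idx, columns=idx)
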