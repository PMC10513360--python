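import numpy as np
import pytest
import scipy.sparse as sp

from compot import CategoricalAnnotation, CountMatrix


@pytest.fixture
def small_counts():
    """4 observations x 3 genes with simple integer counts."""
    values = np.array(
        [
            [2, 0, 1],
            [0, 2, 0],
            [1, 1, 1],
            [4, 0, 0],
        ],
        dtype=float,
    )
    return CountMatrix(
        [f"obs{i}" for i in range(4)], ["gA", "gB", "gC"], sp.csr_matrix(values)
    )


@pytest.fixture
def small_anno():
    return CategoricalAnnotation(
        [f"obs{i}" for i in range(4)], ["t1", "t2", "t1", "t1"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
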