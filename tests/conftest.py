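import numpy as np
import pytest

from d3e.io_counts import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts():
    """4 genes x 6 cells, two groups, one all-zero gene, one spike-in-like row."""
    counts = np.array(
        [
            [0, 1, 2, 3, 1, 0],
            [5, 4, 6, 5, 7, 6],
            [0, 0, 0, 0, 0, 0],
            [2, 2, 2, 2, 2, 2],
        ]
    )
    return CountMatrix.from_arrays(
        counts, groups=["A", "A", "A", "B", "B", "B"],
        gene_ids=["g1", "g2", "gzero", "ERCC-1"],
    )
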