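import numpy as np
import pytest

from scdlc.simulate import ClassLabels, CountMatrix


@pytest.fixture
def tiny_matrix():
    """3 genes x 6 cells, two balanced classes; gene 0 carries the
    class-1-vs-2 values (1,2,3)/(4,5,6) used by the worked BW example."""
    counts = np.array([
        [1, 2, 3, 4, 5, 6],
        [7, 7, 7, 7, 7, 7],       # constant gene
        [1, 3, 2, 0, 4, 2],       # class means both 2 -> zero numerator
    ])
    matrix = CountMatrix(counts=counts,
                         gene_ids=["g1", "g2", "g3"],
                         cell_ids=[f"c{i}" for i in range(1, 7)])
    labels = ClassLabels(labels=np.array([0, 0, 0, 1, 1, 1]),
                         class_names=["A", "B"])
    return matrix, labels


def random_dataset(rng, g=50, n=40, k=2, max_count=30):
    """Seeded random integer count matrix with balanced class labels."""
    counts = rng.integers(0, max_count, size=(g, n))
    matrix = CountMatrix(counts=counts,
                         gene_ids=[f"g{j}" for j in range(g)],
                         cell_ids=[f"c{i}" for i in range(n)])
    codes = np.repeat(np.arange(k), n // k)
    codes = np.concatenate([codes, rng.integers(0, k, size=n - codes.size)])
    labels = ClassLabels(labels=codes, class_names=[chr(65 + c) for c in range(k)])
    return matrix, labels
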