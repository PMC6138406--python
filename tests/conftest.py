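import numpy as np
import pytest

from elmcc import ExpressionMatrix, SimConfig, simulate_cohort


@pytest.fixture
def small_expr():
    """3 genes x 4 samples toy matrix."""
    return ExpressionMatrix(
        gene_ids=["G1", "G2", "G3"],
        sample_ids=["A", "B", "C", "D"],
        values=np.array(
            [[1.0, 2.0, 3.0, 4.0],
             [5.0, 5.0, 5.0, 5.0],
             [0.5, 1.5, 2.5, 7.5]]
        ),
    )


def make_blobs3d(seed=0, n_per=30, k=4, sep=12.0, sd=0.5):
    """k well-separated Gaussian blobs in 3-D, centers >= `sep` apart."""
    rng = np.random.default_rng(seed)
    centers = np.array(
        [[0, 0, 0], [sep, 0, 0], [0, sep, 0], [0, 0, sep], [sep, sep, sep]]
    )[:k]
    X = np.vstack([c + rng.normal(0, sd, (n_per, 3)) for c in centers])
    labels = np.repeat(np.arange(1, k + 1), n_per)
    return X, labels


@pytest.fixture
def blobs4():
    return make_blobs3d(seed=11)


@pytest.fixture
def default_cohort():
    return simulate_cohort(SimConfig(seed=3))


def blob_expression(seed=0, k=4, n_per=25, n_genes=12, sep=20.0, sd=0.5):
    """Expression matrix whose samples form k well-separated blobs."""
    rng = np.random.default_rng(seed)
    centers = rng.uniform(-1, 1, (k, n_genes))
    centers *= sep / 2  # pairwise distances comfortably >> within-spread
    X = np.vstack([c + rng.normal(0, sd, (n_per, n_genes)) for c in centers])
    labels = np.repeat(np.arange(1, k + 1), n_per)
    genes = [f"G{i+1}" for i in range(n_genes)]
    samples = [f"S{i+1}" for i in range(k * n_per)]
    return ExpressionMatrix(genes, samples, X.T), labels
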