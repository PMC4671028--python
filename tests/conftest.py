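import numpy as np
import pytest

from restnet.graphs import BinaryGraph
from restnet.synthetic import SyntheticCohortSpec, generate_cohort


def random_graph(n: int, p: float, rng: np.random.Generator) -> BinaryGraph:
    """Erdős–Rényi fixture used by oracle-equivalence tests."""
    upper = np.triu(rng.random((n, n)) < p, k=1).astype(np.uint8)
    return BinaryGraph(upper | upper.T)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A trimmed default-structure cohort shared by integration tests."""
    spec = SyntheticCohortSpec(n_subjects=8, seed=123)
    return generate_cohort(spec)


@pytest.fixture
def two_k5():
    """Two disconnected 5-cliques: Q = 0.5 under the clique partition."""
    A = np.zeros((10, 10), dtype=np.uint8)
    A[:5, :5] = 1
    A[5:, 5:] = 1
    np.fill_diagonal(A, 0)
    return BinaryGraph(A)
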