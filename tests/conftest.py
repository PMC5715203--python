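import numpy as np
import pytest

from ahpgroup.hierarchy import Hierarchy, build_default_hierarchy


@pytest.fixture(scope="session")
def default_hierarchy() -> Hierarchy:
    return build_default_hierarchy()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_reciprocal_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random positive reciprocal matrix with off-grid (continuous) entries."""
    a = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a[i, j] = np.exp(rng.normal(0.0, 1.0))
            a[j, i] = 1.0 / a[i, j]
    return a


def consistent_matrix(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    return w[:, None] / w[None, :]
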