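import numpy as np
import pytest

from decost.model_builder import InteractionRecord, build_adjacency, normalize_dynamics


def random_stable_matrix(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Random dense matrix rescaled to an exact target spectral radius."""
    M = rng.normal(size=(n, n))
    rho = np.max(np.abs(np.linalg.eigvals(M)))
    return M * (radius / rho)


@pytest.fixture
def two_gene_model():
    records = [
        InteractionRecord(source="A", target="B", mechanism="activation"),
        InteractionRecord(source="B", target="A", mechanism="inhibition"),
    ]
    return normalize_dynamics(build_adjacency(records))


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)
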