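import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bicmkit import BipartiteGraph

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

TOY_MATRIX = np.array([[1, 1, 0], [1, 0, 0]])
NESTED3 = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])


@pytest.fixture
def toy() -> BipartiteGraph:
    """2x3 example: c1 -> {p1, p2}, c2 -> {p1}."""
    return BipartiteGraph.from_matrix(
        TOY_MATRIX, ["c1", "c2"], ["p1", "p2", "p3"]
    )


@pytest.fixture
def nested3() -> BipartiteGraph:
    """Perfectly nested 3x3 triangle."""
    return BipartiteGraph.from_matrix(NESTED3)


def random_graph(rng: np.random.Generator, n_rows: int, n_cols: int, p: float = 0.4) -> BipartiteGraph:
    return BipartiteGraph.from_matrix((rng.random((n_rows, n_cols)) < p).astype(int))
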