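import warnings

import numpy as np
import pytest

from socsel.netmetrics import InteractionNetwork


@pytest.fixture(autouse=True)
def _quiet_degenerate_warnings():
    """Degenerate-variance warnings are expected on tiny synthetic groups."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="zero-variance intra-group", category=UserWarning
        )
        yield


def random_adjacency(rng: np.random.Generator, n: int, p: float = 0.45) -> np.ndarray:
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i, j] = adj[j, i] = True
    return adj


def network_from_adjacency(adj: np.ndarray, year: int = 2000) -> InteractionNetwork:
    """Directed network whose undirected simplification equals ``adj``."""
    return InteractionNetwork(
        year=year,
        group_index=0,
        nodes=tuple(f"n{i}" for i in range(len(adj))),
        weights=np.triu(adj, 1).astype(int),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
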