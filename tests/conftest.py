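import numpy as np
import pytest

from transcriptogram.network import InteractionNetwork


@pytest.fixture
def path3():
    """Path graph g1 - g2 - g3."""
    return InteractionNetwork.from_edges([("g1", "g2"), ("g2", "g3")])


@pytest.fixture
def path6():
    """Path graph on six genes."""
    return InteractionNetwork.from_edges([(f"g{i}", f"g{i+1}") for i in range(1, 6)])


@pytest.fixture
def k4():
    """Complete graph on four genes (fully symmetric cost landscape)."""
    genes = [f"g{i}" for i in range(1, 5)]
    return InteractionNetwork.from_edges(
        [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
    )


def random_gnp_network(n: int, p: float, seed: int) -> InteractionNetwork:
    """Erdos-Renyi G(n, p) restricted to genes with degree >= 1."""
    rng = np.random.default_rng(seed)
    names = [f"n{i:03d}" for i in range(n)]
    pairs = [
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    if not pairs:  # guarantee a non-empty network
        pairs = [(names[0], names[1])]
    return InteractionNetwork.from_edges(pairs)
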