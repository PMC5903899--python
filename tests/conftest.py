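import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def single_ffl() -> nx.DiGraph:
    return nx.DiGraph([("a", "b"), ("a", "c"), ("b", "c")])


@pytest.fixture
def two_ffls_sharing_input() -> nx.DiGraph:
    """Two FFLs whose only shared node is the common input a."""
    return nx.DiGraph(
        [("a", "b"), ("a", "c"), ("b", "c"), ("a", "d"), ("a", "e"), ("d", "e")]
    )


@pytest.fixture
def two_disjoint_ffls() -> nx.DiGraph:
    return nx.DiGraph(
        [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("d", "f"), ("e", "f")]
    )


def disjoint_ffls(k: int) -> nx.DiGraph:
    """k node-disjoint feed-forward loops."""
    g = nx.DiGraph()
    for i in range(k):
        g.add_edges_from(
            [(f"a{i}", f"b{i}"), (f"a{i}", f"c{i}"), (f"b{i}", f"c{i}")]
        )
    return g


def random_digraph(n: int, p: float, seed: int) -> nx.DiGraph:
    """Seeded ER digraph with string labels, for oracle comparisons."""
    import numpy as np

    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    labels = [f"v{i}" for i in range(n)]
    g.add_nodes_from(labels)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(labels[i], labels[j])
    return g
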