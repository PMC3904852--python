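import networkx as nx
import numpy as np
import pytest

from culturenet import CLUSTER, BRANCH, build_graph


def random_culture_graph(seed: int, n_max: int = 30, p: float = 0.15,
                         with_b: bool = False):
    """Seeded random two-class graph for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    cls = (
        rng.choice([CLUSTER, BRANCH], size=n, p=[0.7, 0.3])
        if with_b else [CLUSTER] * n
    )
    nodes = [
        (i, cls[i], (float(rng.uniform(-100, 100)), float(rng.uniform(-100, 100))))
        for i in range(n)
    ]
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return build_graph(nodes, edges)


@pytest.fixture
def triangle():
    from culturenet import toy_graph
    return toy_graph("triangle")
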