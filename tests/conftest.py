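import numpy as np
import pytest

from netcrosstalk import Network


@pytest.fixture
def triangle():
    return Network([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def star4():
    """Star K1,3: hub c with three leaves."""
    return Network([("c", "l1"), ("c", "l2"), ("c", "l3")])


@pytest.fixture
def path3():
    return Network([("a", "b"), ("b", "c")])


@pytest.fixture
def cycle4():
    return Network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


def random_simple_network(rng: np.random.Generator, n_nodes=25, p=0.15) -> Network:
    """Erdős–Rényi-style fuzz network (isolated nodes dropped by construction)."""
    edges = []
    names = [f"n{i:02d}" for i in range(n_nodes)]
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                edges.append((names[i], names[j]))
    if not edges:  # ensure at least one link
        edges.append((names[0], names[1]))
    return Network(edges)
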