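import pytest

from gusm import LabeledGraph, random_labeled_graph


def make_random_graphs(count, seed0=0, max_n=30, max_m=60, alphabet="abcd"):
    """Seeded family of random labeled graphs spanning sizes up to the caps."""
    graphs = []
    for i in range(count):
        n = 5 + (seed0 + i * 7) % (max_n - 4)
        m = min(n * (n - 1) // 2, 4 + (seed0 + i * 13) % (max_m - 3))
        k = 1 + i % len(alphabet)
        graphs.append(
            random_labeled_graph(n, m, alphabet[:k], seed=seed0 + i)
        )
    return graphs


@pytest.fixture(scope="session")
def random_graphs():
    return make_random_graphs(20)


@pytest.fixture
def path3():
    """Path v1 - v2 - v3, all labeled 'x'."""
    return LabeledGraph.build(
        {"v1": "x", "v2": "x", "v3": "x"}, [("v1", "v2"), ("v2", "v3")]
    )


@pytest.fixture
def triangle():
    return LabeledGraph.build(
        {"u": "a", "v": "b", "w": "c"}, [("u", "v"), ("v", "w"), ("w", "u")]
    )
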