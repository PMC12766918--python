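import pytest

import netkin as nk


@pytest.fixture
def two_triangles():
    return nk.Network.build(
        list("abcdef"),
        [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")],
    )


@pytest.fixture
def two_k4_bridge():
    """Two K4 cliques joined by one bridge edge (8 nodes, 13 edges)."""
    nodes = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
    edges = [(f"a{i}", f"a{j}") for i in range(4) for j in range(i + 1, 4)]
    edges += [(f"b{i}", f"b{j}") for i in range(4) for j in range(i + 1, 4)]
    edges += [("a3", "b0")]
    return nk.Network.build(nodes, edges)


@pytest.fixture
def clique_partition(two_k4_bridge):
    nodes = two_k4_bridge.nodes
    return nk.Partition.from_labels(nodes, [0 if v.startswith("a") else 1 for v in nodes])


@pytest.fixture
def planted_fixture():
    """4 x 25 SBM with coherent annotation signal (fixed seed)."""
    return nk.gen_planted(4, 25, 0.5, 0.02, seed=11, coherent_terms=True)
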