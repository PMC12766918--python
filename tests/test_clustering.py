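"""Clustering algorithms against hand-derived values, brute-force search,
and networkx as an independent oracle."""

import itertools

import networkx as nx
import numpy as np
import pytest

import netkin as nk

# ----------------------------------------------------------------------
# modularity


def brute_force_modularity(net, part, gamma=1.0):
    """Independent O(n^2) evaluation of the double sum
    (1/2m) sum_ij [A_ij - gamma k_i k_j / 2m] delta(c_i, c_j)."""
    m2 = 2.0 * net.total_weight()
    deg = net.degrees()
    adj = net.adjacency()
    q = 0.0
    for u in net.nodes:
        for v in net.nodes:
            if part.assignment[u] != part.assignment[v]:
                continue
            a_uv = adj[u].get(v, 0.0)
            q += a_uv - gamma * deg[u] * deg[v] / m2
    return q / m2


def test_modularity_one_cluster_is_zero(two_k4_bridge):
    part = nk.Partition.from_labels(two_k4_bridge.nodes, [0] * 8)
    assert nk.modularity(two_k4_bridge, part) == pytest.approx(0.0, abs=1e-12)


def test_modularity_two_k4_bridge_hand_value(two_k4_bridge, clique_partition):
    # 12/13 - 1/2, from direct evaluation of the formula
    expected = 12 / 13 - 0.5
    assert nk.modularity(two_k4_bridge, clique_partition) == pytest.approx(expected)
    assert brute_force_modularity(two_k4_bridge, clique_partition) == pytest.approx(
        expected
    )


def test_modularity_singleton_triangle():
    tri = nk.Network.build("abc", [("a", "b"), ("b", "c"), ("a", "c")])
    part = nk.Partition.from_labels("abc", [0, 1, 2])
    assert nk.modularity(tri, part) == pytest.approx(-1 / 3)


@pytest.mark.parametrize("gamma", [0.5, 1.0, 2.0])
def test_modularity_matches_double_sum_oracle(two_k4_bridge, gamma):
    rng = np.random.default_rng(0)
    for _ in range(5):
        labels = rng.integers(0, 3, 8)
        part = nk.Partition.from_labels(two_k4_bridge.nodes, labels)
        assert nk.modularity(two_k4_bridge, part, gamma) == pytest.approx(
            brute_force_modularity(two_k4_bridge, part, gamma)
        )


def test_modularity_empty_edge_set_errors():
    net = nk.Network.build("ab", [])
    with pytest.raises(ValueError):
        nk.modularity(net, nk.Partition.from_labels("ab", [0, 1]))


# ----------------------------------------------------------------------
# Louvain


def test_louvain_two_triangles(two_triangles):
    part = nk.louvain(two_triangles, seed=0)
    assert part.clusters() == [["a", "b", "c"], ["d", "e", "f"]]


def test_louvain_finds_clique_split(two_k4_bridge, clique_partition):
    part = nk.louvain(two_k4_bridge, seed=0)
    assert part.assignment == clique_partition.assignment
    assert nk.modularity(two_k4_bridge, part) == pytest.approx(12 / 13 - 0.5)


def test_louvain_deterministic_for_fixed_seed(two_k4_bridge):
    a = nk.louvain(two_k4_bridge, seed=7)
    b = nk.louvain(two_k4_bridge, seed=7)
    assert a.assignment == b.assignment


def test_louvain_never_below_singleton_modularity():
    rng = np.random.default_rng(1)
    for trial in range(10):
        g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1e6)))
        if g.number_of_edges() == 0:
            continue
        net = nk.Network.from_networkx(g)
        part = nk.louvain(net, seed=trial)
        singles = nk.Partition.from_labels(net.nodes, range(net.n))
        assert nk.modularity(net, part) >= nk.modularity(net, singles) - 1e-12


def _all_partitions(items):
    """Enumerate all set partitions (restricted growth strings)."""
    n = len(items)

    def rec(i, labels, kmax):
        if i == n:
            yield list(labels)
            return
        for lab in range(kmax + 1):
            labels.append(lab)
            yield from rec(i + 1, labels, max(kmax, lab + 1))
            labels.pop()

    yield from rec(0, [], 0)


def test_louvain_reaches_global_optimum_on_small_graphs():
    """On random graphs with <= 8 nodes, Louvain's Q matches the brute
    force optimum over all partitions in >= 90% of seeded instances."""
    hits = total = 0
    for seed in range(20):
        g = nx.gnp_random_graph(7, 0.4, seed=seed)
        if g.number_of_edges() < 2:
            continue
        net = nk.Network.from_networkx(g)
        best = max(
            nk.modularity(net, nk.Partition.from_labels(net.nodes, labels))
            for labels in _all_partitions(net.nodes)
        )
        q = nk.modularity(net, nk.louvain(net, seed=seed))
        total += 1
        hits += q >= best - 1e-10
    assert hits / total >= 0.9


def test_louvain_matches_networkx_quality(two_k4_bridge):
    """networkx's Louvain (independent implementation) reaches the same
    modularity on the clique fixture."""
    g = two_k4_bridge.to_networkx()
    comms = nx.community.louvain_communities(g, seed=1)
    q_nx = nx.community.modularity(g, comms)
    q = nk.modularity(two_k4_bridge, nk.louvain(two_k4_bridge, seed=1))
    assert q == pytest.approx(q_nx)


# ----------------------------------------------------------------------
# label propagation / greedy


def test_label_propagation_components(two_triangles):
    part = nk.label_propagation(two_triangles, seed=0)
    assert part.clusters() == [["a", "b", "c"], ["d", "e", "f"]]


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_label_propagation_star_single_cluster(seed):
    star = nk.Network.build(
        ["h", "l1", "l2", "l3", "l4", "l5"],
        [("h", f"l{i}") for i in range(1, 6)],
    )
    assert nk.label_propagation(star, seed=seed).k == 1


def test_greedy_modularity_two_triangles(two_triangles):
    assert nk.greedy_modularity(two_triangles).k == 2


def test_greedy_modularity_clique_split(two_k4_bridge, clique_partition):
    part = nk.greedy_modularity(two_k4_bridge)
    assert part.assignment == clique_partition.assignment


def test_greedy_modularity_nonnegative_q():
    rng = np.random.default_rng(2)
    for trial in range(5):
        g = nx.gnp_random_graph(10, 0.4, seed=int(rng.integers(1e6)))
        if g.number_of_edges() == 0:
            continue
        net = nk.Network.from_networkx(g)
        part = nk.greedy_modularity(net)
        assert nk.modularity(net, part) >= -1e-12


# ----------------------------------------------------------------------
# Markov Clustering


def test_mcl_two_triangles(two_triangles):
    part = nk.markov_clustering(two_triangles)
    assert part.clusters() == [["a", "b", "c"], ["d", "e", "f"]]


def test_mcl_single_edge_one_cluster():
    net = nk.Network.build("AB", [("A", "B")])
    part = nk.markov_clustering(net)
    assert part.k == 1 and part.clusters() == [["A", "B"]]


def test_mcl_inflation_never_decreases_cluster_count_on_barbell():
    nodes = [f"x{i}" for i in range(5)] + [f"y{i}" for i in range(5)]
    edges = [(f"x{i}", f"x{j}") for i in range(5) for j in range(i + 1, 5)]
    edges += [(f"y{i}", f"y{j}") for i in range(5) for j in range(i + 1, 5)]
    edges += [("x4", "y0")]
    net = nk.Network.build(nodes, edges)
    counts = [nk.markov_clustering(net, inflation=r).k for r in (1.5, 2.0, 4.0)]
    assert counts == sorted(counts)


def test_mcl_invalid_params():
    net = nk.Network.build("AB", [("A", "B")])
    with pytest.raises(ValueError):
        nk.markov_clustering(net, inflation=1.0)
    with pytest.raises(ValueError):
        nk.markov_clustering(net, expansion=1)


def test_mcl_nonconvergence_raises():
    net = nk.Network.build("ABCD", [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
    with pytest.raises(nk.MCLConvergenceError):
        nk.markov_clustering(net, max_iter=1)


# ----------------------------------------------------------------------
# shared invariants and dispatch


ALGOS = ["louvain", "labelprop", "greedy", "mcl"]


@pytest.mark.parametrize("algo", ALGOS)
def test_partitions_are_exhaustive_disjoint_canonical(algo, two_k4_bridge):
    part = nk.cluster(two_k4_bridge, algo, seed=0)
    part.validate(two_k4_bridge)
    # canonical numbering: clusters ordered by smallest contained node id
    firsts = [min(c) for c in part.clusters()]
    assert firsts == sorted(firsts)


@pytest.mark.parametrize("algo", ALGOS)
def test_clusters_never_span_components(algo):
    rng = np.random.default_rng(3)
    g = nx.gnp_random_graph(8, 0.5, seed=4)
    h = nx.relabel_nodes(nx.gnp_random_graph(7, 0.5, seed=5), lambda i: i + 100)
    net = nk.Network.from_networkx(nx.compose(g, h))
    part = nk.cluster(net, algo, seed=0)
    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(net.to_networkx())):
        for v in comp:
            comp_of[v] = ci
    for cl in part.clusters():
        assert len({comp_of[v] for v in cl}) == 1


def test_dispatch_identity(two_k4_bridge):
    assert (
        nk.cluster(two_k4_bridge, "louvain", seed=5).assignment
        == nk.louvain(two_k4_bridge, seed=5).assignment
    )


def test_dispatch_unknown_algorithm(two_k4_bridge):
    with pytest.raises(ValueError, match="unknown"):
        nk.cluster(two_k4_bridge, "quantum")


def test_backend_unavailable_lists_native_options(two_k4_bridge, monkeypatch):
    import netkin.clustering as cl

    monkeypatch.setattr(cl, "_BACKENDS", {})
    with pytest.raises(nk.BackendUnavailableError, match="louvain"):
        nk.cluster(two_k4_bridge, "spinglass")


def test_leiden_backend_partitions_cliques(two_k4_bridge, clique_partition):
    pytest.importorskip("leidenalg")
    part = nk.cluster(two_k4_bridge, "leiden", seed=0)
    assert part.assignment == clique_partition.assignment


def test_planted_sbm_recovery_louvain_and_mcl():
    """Louvain and MCL both recover the planted blocks exactly on a
    well-separated SBM (spot check; the full 100-replicate sweep runs in
    the acceptance suite)."""
    for seed in range(10):
        net, truth, _ = nk.gen_planted(4, 25, 0.5, 0.02, seed=seed)
        assert nk.adjusted_rand_index(nk.louvain(net, seed=seed), truth) == 1.0
        assert nk.adjusted_rand_index(nk.markov_clustering(net), truth) == 1.0


def test_partition_tsv_round_trip(tmp_path, two_k4_bridge):
    part = nk.louvain(two_k4_bridge, seed=0)
    p = tmp_path / "part.tsv"
    nk.write_partition(part, p)
    back = nk.read_partition(p)
    assert back.assignment == part.assignment
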