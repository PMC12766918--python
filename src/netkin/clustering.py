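"""Community detection: native Louvain, label propagation, greedy
modularity agglomeration, and Markov Clustering, plus a backend registry
for algorithms delegated to igraph (Leiden, Spinglass, Walktrap).

Determinism contract: every stochastic choice is driven by the caller's
seed (node-visit orders are seeded shuffles) and every tie is broken
deterministically (smallest community id / lexicographic node id), so a
fixed seed reproduces the partition bit-for-bit.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .network import Network

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "modularity",
    "louvain",
    "label_propagation",
    "greedy_modularity",
    "markov_clustering",
    "cluster",
    "register_backend",
    "BackendUnavailableError",
    "MCLConvergenceError",
    "read_partition",
    "write_partition",
]

NATIVE_ALGORITHMS = ("louvain", "labelprop", "greedy", "mcl")


class BackendUnavailableError(RuntimeError):
    pass


class MCLConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"Markov Clustering did not converge in {max_iter} iterations "
            f"(last residual {residual:.3e})"
        )


@dataclass
class Partition:
    """Disjoint, exhaustive node-to-cluster assignment.

    Cluster ids are contiguous ``0..k-1`` and canonically numbered:
    clusters are ordered by their lexicographically smallest member.
    """

    assignment: dict[str, int]
    k: int
    params: dict = field(default_factory=dict)

    @classmethod
    def from_labels(cls, nodes, labels, params=None) -> "Partition":
        """Build from arbitrary hashable labels, renumbering canonically."""
        pairs = sorted(zip(map(str, nodes), labels))
        relabel: dict = {}
        assignment = {}
        for node, lab in pairs:
            if lab not in relabel:
                relabel[lab] = len(relabel)
            assignment[node] = relabel[lab]
        return cls(assignment, k=len(relabel), params=dict(params or {}))

    def clusters(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.k)]
        for node in sorted(self.assignment):
            out[self.assignment[node]].append(node)
        return out

    def sizes(self) -> np.ndarray:
        s = np.zeros(self.k, dtype=np.int64)
        for c in self.assignment.values():
            s[c] += 1
        return s

    def labels_for(self, nodes) -> np.ndarray:
        return np.array([self.assignment[v] for v in nodes], dtype=np.int64)

    def indicator(self, nodes) -> sp.csr_matrix:
        """Sparse k x N cluster indicator aligned to ``nodes`` order."""
        lab = self.labels_for(nodes)
        n = len(lab)
        return sp.csr_matrix(
            (np.ones(n, dtype=np.int8), (lab, np.arange(n))), shape=(self.k, n)
        )

    def validate(self, net: Network) -> None:
        if set(self.assignment) != set(net.nodes):
            raise ValueError("partition does not cover exactly the network nodes")
        seen = set(self.assignment.values())
        if seen != set(range(self.k)):
            raise ValueError("cluster ids not contiguous 0..k-1")


# ----------------------------------------------------------------------
# modularity


def modularity(net: Network, part: Partition, gamma: float = 1.0) -> float:
    """Newman-Girvan modularity with resolution gamma.

    Q = sum_c [ W_c / m  -  gamma * (d_c / 2m)^2 ]

    where W_c is the intra-cluster edge weight, d_c the total (weighted)
    degree of cluster c, and m the total edge weight.
    """
    if net.m == 0:
        raise ValueError("modularity undefined for an empty edge set")
    m = net.total_weight()
    deg = net.degrees(weighted=True)
    w_in = np.zeros(part.k)
    d_tot = np.zeros(part.k)
    a = part.assignment
    for (u, v), w in net.edges.items():
        if a[u] == a[v]:
            w_in[a[u]] += w
    for v, d in deg.items():
        d_tot[a[v]] += d
    return float((w_in / m).sum() - gamma * ((d_tot / (2.0 * m)) ** 2).sum())


# ----------------------------------------------------------------------
# Louvain


def _louvain_one_level(adj, self_w, deg, m2, gamma, rng):
    """One level of local moving. ``adj`` is a list of {j: w} neighbor maps
    (no self entries); ``self_w`` holds node self-loop weight (counted
    twice in degree, as in aggregated graphs). Returns (community labels,
    improved?)."""
    n = len(adj)
    comm = list(range(n))
    tot = [deg[i] for i in range(n)]  # total degree per community
    order = list(range(n))
    improved = False
    moved = True
    while moved:
        moved = False
        rng.shuffle(order)
        for i in order:
            ci = comm[i]
            ki = deg[i]
            # weights from i to each neighboring community
            links: dict[int, float] = {}
            for j, w in adj[i].items():
                links[comm[j]] = links.get(comm[j], 0.0) + w
            tot[ci] -= ki
            best_c, best_gain = ci, links.get(ci, 0.0) - gamma * ki * tot[ci] / m2
            for c, w_ic in links.items():
                gain = w_ic - gamma * ki * tot[c] / m2
                if gain > best_gain + 1e-12 or (
                    abs(gain - best_gain) <= 1e-12 and c < best_c
                ):
                    best_c, best_gain = c, gain
            tot[best_c] += ki
            if best_c != ci:
                comm[i] = best_c
                moved = True
                improved = True
    return comm, improved


def _aggregate(adj, self_w, comm):
    """Collapse communities into super-nodes; intra weights become
    self-loops."""
    relabel: dict[int, int] = {}
    for i in range(len(adj)):
        relabel.setdefault(comm[i], len(relabel))
    k = len(relabel)
    new_adj: list[dict[int, float]] = [{} for _ in range(k)]
    new_self = [0.0] * k
    for i in range(len(adj)):
        ci = relabel[comm[i]]
        new_self[ci] += self_w[i]
        for j, w in adj[i].items():
            cj = relabel[comm[j]]
            if ci == cj:
                if i < j:
                    new_self[ci] += w
            else:
                new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
    mapping = [relabel[c] for c in comm]
    return new_adj, new_self, mapping


def louvain(net: Network, gamma: float = 1.0, seed: int = 0) -> Partition:
    """Louvain modularity optimization (local moving + aggregation).

    The result's modularity is never below the singleton partition's
    (moves are accepted only on strictly positive gain). Deterministic for
    a fixed seed.
    """
    if net.n == 0:
        raise ValueError("empty graph")
    nodes = net.nodes
    index = {v: i for i, v in enumerate(nodes)}
    adj: list[dict[int, float]] = [{} for _ in nodes]
    for (u, v), w in net.edges.items():
        adj[index[u]][index[v]] = w
        adj[index[v]][index[u]] = w
    self_w = [0.0] * net.n
    m = net.total_weight()
    if m == 0:
        # edgeless graph: every node its own cluster
        return Partition.from_labels(
            nodes, range(net.n), {"algorithm": "louvain", "gamma": gamma, "seed": seed}
        )
    m2 = 2.0 * m
    rng = random.Random(seed)

    node_comm = list(range(net.n))  # original node -> current community label
    while True:
        deg = [sum(a.values()) + 2.0 * s for a, s in zip(adj, self_w)]
        comm, improved = _louvain_one_level(adj, self_w, deg, m2, gamma, rng)
        if not improved:
            break
        adj, self_w, mapping = _aggregate(adj, self_w, comm)
        node_comm = [mapping[c] for c in node_comm]
        if len(adj) == 1:
            break
    return Partition.from_labels(
        nodes,
        [node_comm[index[v]] for v in nodes],
        {"algorithm": "louvain", "gamma": gamma, "seed": seed},
    )


# ----------------------------------------------------------------------
# label propagation


def label_propagation(net: Network, seed: int = 0, max_rounds: int = 1000) -> Partition:
    """Asynchronous label propagation with seeded update order.

    Each node adopts the plurality (weighted) label among its neighbors;
    ties are broken toward the smallest label. Isolated nodes keep their
    own label. Converges when a full pass changes nothing.
    """
    if net.n == 0:
        raise ValueError("empty graph")
    nodes = net.nodes
    index = {v: i for i, v in enumerate(nodes)}
    adj = net.adjacency()
    labels = list(range(net.n))
    rng = random.Random(seed)
    order = list(range(net.n))
    for _ in range(max_rounds):
        rng.shuffle(order)
        changed = False
        for i in order:
            nbrs = adj[nodes[i]]
            if not nbrs:
                continue
            counts: dict[int, float] = {}
            for u, w in nbrs.items():
                lab = labels[index[u]]
                counts[lab] = counts.get(lab, 0.0) + w
            best = max(counts.values())
            new = min(lab for lab, c in counts.items() if c >= best - 1e-12)
            if new != labels[i]:
                labels[i] = new
                changed = True
        if not changed:
            break
    return Partition.from_labels(
        nodes, labels, {"algorithm": "labelprop", "seed": seed}
    )


# ----------------------------------------------------------------------
# greedy modularity (CNM-style agglomeration)


def greedy_modularity(net: Network, gamma: float = 1.0) -> Partition:
    """Agglomerative modularity maximization: repeatedly merge the pair of
    communities with the largest positive modularity gain, ties broken by
    the smallest (i, j) community-id pair. Deterministic (no seed)."""
    if net.n == 0:
        raise ValueError("empty graph")
    m = net.total_weight()
    if m == 0:
        return Partition.from_labels(
            net.nodes, range(net.n), {"algorithm": "greedy", "gamma": gamma}
        )
    index = {v: i for i, v in enumerate(net.nodes)}
    # e[i][j]: fraction of edge weight between communities i, j (i != j)
    e: dict[int, dict[int, float]] = {i: {} for i in range(net.n)}
    a = [0.0] * net.n  # fraction of degree
    for (u, v), w in net.edges.items():
        i, j = index[u], index[v]
        e[i][j] = e[i].get(j, 0.0) + w / (2.0 * m)
        e[j][i] = e[j].get(i, 0.0) + w / (2.0 * m)
        a[i] += w / (2.0 * m)
        a[j] += w / (2.0 * m)

    alive = set(range(net.n))
    parent = list(range(net.n))
    while len(alive) > 1:
        best = None  # (gain, i, j)
        for i in sorted(alive):
            for j in sorted(e[i]):
                if j <= i or j not in alive:
                    continue
                eij = e[i][j]
                gain = 2.0 * (eij - gamma * a[i] * a[j])
                if best is None or gain > best[0] + 1e-15:
                    best = (gain, i, j)
        if best is None or best[0] <= 1e-15:
            break
        _, i, j = best
        # merge j into i
        for t, w in e[j].items():
            if t == i or t not in alive:
                continue
            e[i][t] = e[i].get(t, 0.0) + w
            e[t][i] = e[t].get(i, 0.0) + w
            e[t].pop(j, None)
        e[i].pop(j, None)
        a[i] += a[j]
        alive.discard(j)
        parent[j] = i

    def root(x):
        while parent[x] != x:
            x = parent[x]
        return x

    return Partition.from_labels(
        net.nodes,
        [root(index[v]) for v in net.nodes],
        {"algorithm": "greedy", "gamma": gamma},
    )


# ----------------------------------------------------------------------
# Markov Clustering


def markov_clustering(
    net: Network,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> Partition:
    """Markov Clustering (MCL) on the column-stochastic transition matrix.

    A self-loop of weight 1 is added to every node before normalization.
    Expansion (matrix power ``expansion``) and inflation (entrywise power
    ``inflation`` followed by column renormalization) alternate until the
    matrix is idempotent within ``tol``. Attractor rows define clusters;
    nodes attracted to several systems are assigned to the lowest-id
    cluster (logged).
    """
    if net.n == 0:
        raise ValueError("empty graph")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if expansion < 2:
        raise ValueError("expansion must be >= 2")
    n = net.n
    index = {v: i for i, v in enumerate(net.nodes)}
    rows, cols, data = [], [], []
    for (u, v), w in net.edges.items():
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        data += [w, w]
    rows += list(range(n))
    cols += list(range(n))
    data += [1.0] * n  # self-loops
    M = sp.csc_matrix((data, (rows, cols)), shape=(n, n))
    M = _col_normalize(M)

    residual = np.inf
    for _ in range(max_iter):
        prev = M
        E = M
        for _ in range(expansion - 1):
            E = E @ M
        E = E.tocsc()
        E.data = np.power(E.data, inflation)
        E.data[E.data < prune_threshold] = 0.0
        E.eliminate_zeros()
        M = _col_normalize(E)
        residual = abs(M - prev).max() if (M - prev).nnz else 0.0
        if residual <= tol:
            break
    else:
        raise MCLConvergenceError(residual, max_iter)

    return _interpret_mcl(M, net, inflation, expansion)


def _col_normalize(M: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(M.sum(axis=0)).ravel()
    empty = sums == 0
    if empty.any():
        # re-seed vanished columns with identity so every node stays reachable
        idx = np.where(empty)[0]
        M = (M + sp.csc_matrix(
            (np.ones(len(idx)), (idx, idx)), shape=M.shape
        )).tocsc()
        sums = np.asarray(M.sum(axis=0)).ravel()
    D = sp.diags(1.0 / sums)
    return (M @ D).tocsc()


def _interpret_mcl(M, net, inflation, expansion) -> Partition:
    n = M.shape[0]
    coo = M.tocoo()
    attractors = sorted(set(coo.row))  # rows with outgoing mass
    # union attractors that appear in each other's support
    parent = {i: i for i in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    supports: dict[int, list[int]] = {i: [] for i in attractors}
    for r, c in zip(coo.row, coo.col):
        supports[r].append(c)
    for i in attractors:
        for j in supports[i]:
            if j in parent:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    system_of = {i: find(i) for i in attractors}
    system_ids = sorted(set(system_of.values()))
    sys_index = {s: t for t, s in enumerate(system_ids)}

    labels = [-1] * n
    n_overlap = 0
    for i in attractors:
        s = sys_index[system_of[i]]
        for j in supports[i]:
            if labels[j] == -1:
                labels[j] = s
            elif labels[j] != s:
                n_overlap += 1
                labels[j] = min(labels[j], s)
    next_free = len(system_ids)
    for j in range(n):
        if labels[j] == -1:  # unreachable column (should not happen)
            labels[j] = next_free
            next_free += 1
    if n_overlap:
        logger.info(
            "MCL: %d node(s) attracted to multiple systems assigned to the "
            "lowest-id cluster",
            n_overlap,
        )
    return Partition.from_labels(
        net.nodes,
        labels,
        {"algorithm": "mcl", "inflation": inflation, "expansion": expansion},
    )


# ----------------------------------------------------------------------
# dispatch and backends

_BACKENDS: dict[str, object] = {}


def register_backend(name: str, fn) -> None:
    """Register ``fn(net, **params) -> Partition`` under ``name``."""
    _BACKENDS[name.lower()] = fn


def _igraph_backend(method: str):
    def run(net: Network, **params) -> Partition:
        try:
            import igraph as ig
        except ImportError as e:  # pragma: no cover
            raise BackendUnavailableError(
                f"{method} requires python-igraph; native algorithms: "
                f"{', '.join(NATIVE_ALGORITHMS)}"
            ) from e
        index = {v: i for i, v in enumerate(net.nodes)}
        edges = [(index[u], index[v]) for (u, v) in net.edges]
        weights = list(net.edges.values())
        g = ig.Graph(n=net.n, edges=edges)
        seed = int(params.get("seed", 0))
        if method == "leiden":
            try:
                import leidenalg as la
            except ImportError as e:  # pragma: no cover
                raise BackendUnavailableError(
                    "leiden requires leidenalg; native algorithms: "
                    f"{', '.join(NATIVE_ALGORITHMS)}"
                ) from e
            part = la.find_partition(
                g,
                la.RBConfigurationVertexPartition,
                weights=weights,
                resolution_parameter=float(params.get("gamma", 1.0)),
                seed=seed,
            )
            labels = part.membership
        elif method == "spinglass":
            import random as _r

            _r.seed(seed)
            labels = g.community_spinglass(weights=weights).membership
        elif method == "walktrap":
            labels = g.community_walktrap(
                weights=weights, steps=int(params.get("steps", 4))
            ).as_clustering().membership
        else:  # pragma: no cover
            raise ValueError(method)
        return Partition.from_labels(
            net.nodes, labels, {"algorithm": method, **params}
        )

    return run


for _name in ("leiden", "spinglass", "walktrap"):
    try:
        import igraph  # noqa: F401

        register_backend(_name, _igraph_backend(_name))
    except ImportError:  # pragma: no cover
        pass


def cluster(net: Network, algorithm: str = "louvain", **params) -> Partition:
    """Dispatch to a clustering algorithm by name.

    Native: ``louvain``, ``labelprop``, ``greedy``, ``mcl``. Delegated
    (when a backend is registered): ``leiden``, ``spinglass``,
    ``walktrap``. Parameters are recorded in ``Partition.params``.
    """
    algorithm = algorithm.lower()
    if algorithm == "louvain":
        return louvain(
            net, gamma=float(params.get("gamma", 1.0)), seed=int(params.get("seed", 0))
        )
    if algorithm in ("labelprop", "label_propagation"):
        return label_propagation(net, seed=int(params.get("seed", 0)))
    if algorithm in ("greedy", "greedy_modularity"):
        return greedy_modularity(net, gamma=float(params.get("gamma", 1.0)))
    if algorithm == "mcl":
        return markov_clustering(
            net,
            inflation=float(params.get("inflation", 2.0)),
            expansion=int(params.get("expansion", 2)),
            prune_threshold=float(params.get("prune_threshold", 1e-5)),
            max_iter=int(params.get("max_iter", 200)),
            tol=float(params.get("tol", 1e-8)),
        )
    if algorithm in _BACKENDS:
        return _BACKENDS[algorithm](net, **params)
    if algorithm in ("leiden", "spinglass", "walktrap"):
        raise BackendUnavailableError(
            f"no backend registered for {algorithm!r}; native algorithms: "
            f"{', '.join(NATIVE_ALGORITHMS)}"
        )
    raise ValueError(f"unknown clustering algorithm {algorithm!r}")


# ----------------------------------------------------------------------
# partition TSV I/O (node <tab> cluster)


def write_partition(part: Partition, path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tcluster\n")
        for node in sorted(part.assignment):
            fh.write(f"{node}\t{part.assignment[node]}\n")


def read_partition(path) -> Partition:
    import csv

    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty partition file")
        rows = list(reader)
        if header and header[0] != "node":  # headerless file
            rows.insert(0, header)
    nodes = [r[0] for r in rows]
    labels = [int(r[1]) for r in rows]
    return Partition.from_labels(nodes, labels)
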