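"""Synthetic benchmark inputs: scale-free networks, null annotation
tables, and planted-partition fixtures with coherent annotation signal.

The scale-free generator is preferential attachment seeded with a
complete graph on max(3, m+1) nodes, so the edge count is closed-form:
with m = 2 (triangle seed) a graph on n nodes has exactly
3 + 2(n - 3) = 2n - 3 edges — the "twice as many edges as nodes" regime
used for scalability benchmarking.

The annotation generator emulates GO-BP-like term tables: term sizes are
drawn i.i.d. from a heavy-tailed distribution (default: discrete power
law with exponent 1.5 truncated to [5, n/10]) and members are sampled
uniformly without replacement, independent of topology — a null model by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .annotation import AnnotationMatrix
from .clustering import Partition
from .network import Network

logger = logging.getLogger(__name__)

__all__ = [
    "TermSizeDist",
    "gen_scale_free",
    "gen_annotations",
    "gen_planted",
]


@dataclass
class TermSizeDist:
    """Term-size distribution spec: ``powerlaw`` (P(s) ~ s^-exponent) or
    ``lognormal`` (mu/sigma on the log scale), truncated to [min, max]."""

    law: str = "powerlaw"
    exponent: float = 1.5
    mu: float = 3.0
    sigma: float = 1.0
    min_size: int = 5
    max_size: int | None = None  # defaults to n_nodes // 10

    def sample(self, n_terms: int, n_nodes: int, rng: np.random.Generator):
        lo = self.min_size
        hi = self.max_size if self.max_size is not None else max(lo, n_nodes // 10)
        if lo > hi or hi > n_nodes:
            raise ValueError(f"infeasible term-size bounds [{lo}, {hi}] for n={n_nodes}")
        support = np.arange(lo, hi + 1)
        if self.law == "powerlaw":
            w = support.astype(float) ** (-self.exponent)
        elif self.law == "lognormal":
            w = np.exp(
                -((np.log(support) - self.mu) ** 2) / (2.0 * self.sigma**2)
            ) / support
        else:
            raise ValueError(f"unknown size law {self.law!r}")
        w /= w.sum()
        return rng.choice(support, size=n_terms, p=w)


def gen_scale_free(n: int, m: int = 2, seed: int = 0) -> Network:
    """Preferential-attachment scale-free graph.

    Seeded with a complete graph on ``max(3, m + 1)`` nodes (a triangle
    for m = 2); each arriving node attaches to ``m`` distinct existing
    nodes chosen with probability proportional to degree. Connected by
    construction; node ids are zero-padded so lexicographic order matches
    arrival order.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if n <= m:
        raise ValueError(f"n must exceed m (got n={n}, m={m})")
    rng = np.random.default_rng(seed)
    seed_size = min(n, max(3, m + 1))
    width = len(str(n - 1))
    ids = [f"v{i:0{width}d}" for i in range(n)]

    edges: list[tuple[str, str]] = [
        (ids[i], ids[j]) for i in range(seed_size) for j in range(i + 1, seed_size)
    ]
    # repeated-node list: node i appears deg(i) times
    repeated = [i for i in range(seed_size) for _ in range(seed_size - 1)]
    for new in range(seed_size, n):
        targets: set[int] = set()
        while len(targets) < m:
            draw = rng.integers(0, len(repeated), size=m - len(targets))
            for d in draw:
                targets.add(repeated[d])
        for t in sorted(targets):
            edges.append((ids[t], ids[new]))
            repeated.append(t)
        repeated.extend([new] * m)
    return Network.build(ids, edges)


def gen_annotations(
    net: Network,
    n_terms: int = 1000,
    dist: TermSizeDist | None = None,
    seed: int = 0,
) -> AnnotationMatrix:
    """Simulated annotation table: ``n_terms`` terms with heavy-tailed
    sizes, members drawn uniformly without replacement, independent of
    topology."""
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    dist = dist or TermSizeDist()
    rng = np.random.default_rng(seed)
    sizes = dist.sample(n_terms, net.n, rng)
    rows, cols = [], []
    for j, s in enumerate(sizes):
        members = rng.choice(net.n, size=int(s), replace=False)
        rows.extend(members.tolist())
        cols.extend([j] * int(s))
    width = len(str(n_terms - 1))
    term_ids = tuple(f"T{j:0{width}d}" for j in range(n_terms))
    mat = sp.csc_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(net.n, n_terms),
    )
    return AnnotationMatrix(matrix=mat, term_ids=term_ids, node_ids=net.nodes)


def gen_planted(
    blocks: int = 4,
    size: int = 25,
    p_in: float = 0.5,
    p_out: float = 0.02,
    seed: int = 0,
    coherent_terms: bool = False,
    n_decoys: int = 20,
):
    """Planted-partition (stochastic block model) fixture.

    Returns ``(network, ground_truth_partition, annotation_matrix)``;
    the matrix is ``None`` unless ``coherent_terms``. With coherent
    terms, each block gets one signal term covering a seeded 80% subset
    of the block, plus ``n_decoys`` decoy terms of uniform random nodes.
    """
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("require 0 <= p_out < p_in <= 1")
    if p_out == 0:
        logger.warning("p_out=0: blocks are expected to be disconnected components")
    import networkx as nx

    n = blocks * size
    probs = [
        [p_in if i == j else p_out for j in range(blocks)] for i in range(blocks)
    ]
    g = nx.stochastic_block_model([size] * blocks, probs, seed=int(seed))
    width = len(str(n - 1))
    ids = [f"v{i:0{width}d}" for i in range(n)]
    net = Network.build(ids, [(ids[u], ids[v]) for u, v in g.edges()])
    truth = Partition.from_labels(
        ids,
        [i // size for i in range(n)],
        {"algorithm": "planted", "seed": seed},
    )

    matrix = None
    if coherent_terms:
        rng = np.random.default_rng(seed + 1)
        rows, cols, term_ids = [], [], []
        for b in range(blocks):
            members = rng.choice(
                np.arange(b * size, (b + 1) * size),
                size=max(1, int(round(0.8 * size))),
                replace=False,
            )
            j = len(term_ids)
            term_ids.append(f"signal_{b}")
            rows.extend(members.tolist())
            cols.extend([j] * len(members))
        for d in range(n_decoys):
            s = int(rng.integers(5, 16))
            members = rng.choice(n, size=s, replace=False)
            j = len(term_ids)
            term_ids.append(f"decoy_{d:02d}")
            rows.extend(members.tolist())
            cols.extend([j] * s)
        mat = sp.csc_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)),
            shape=(n, len(term_ids)),
        )
        matrix = AnnotationMatrix(
            matrix=mat, term_ids=tuple(term_ids), node_ids=net.nodes
        )
    return net, truth, matrix
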