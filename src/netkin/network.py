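"""Canonical undirected network container.

All downstream matrices (annotation membership, cluster indicators) index
rows by the canonical node order, which is lexicographic by node id so that
results are bit-reproducible regardless of input file ordering.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)


class NetworkValidationError(ValueError):
    """Raised when input violates the network invariants."""


class Network:
    """An undirected, simple, weighted graph with optional 2-D coordinates.

    Invariants (enforced by :meth:`build`):

    * no self-loops; parallel/duplicate edges collapsed with weights summed
    * every edge endpoint is a known node id
    * node order is lexicographic and stable
    * if coordinates are present, every node has exactly one finite pair

    Parameters are trusted as already normalized; use :meth:`build` to
    construct from raw data.
    """

    def __init__(
        self,
        nodes: tuple[str, ...],
        edges: dict[tuple[str, str], float],
        coords: dict[str, tuple[float, float]] | None = None,
        labels: dict[str, str] | None = None,
    ):
        self.nodes = nodes
        self.edges = edges
        self.coords = coords
        self.labels = labels
        self._index = {v: i for i, v in enumerate(nodes)}
        self._adj: dict[str, dict[str, float]] | None = None

    # ------------------------------------------------------------------
    @classmethod
    def build(
        cls,
        nodes: Iterable[str],
        edges: Iterable[tuple],
        coords: Mapping[str, tuple[float, float]] | None = None,
        labels: Mapping[str, str] | None = None,
    ) -> "Network":
        """Normalize raw nodes/edges into a canonical :class:`Network`.

        ``edges`` yields ``(u, v)`` or ``(u, v, weight)``. Directed input is
        symmetrized (an arc u->v becomes the undirected edge {u, v});
        duplicate and anti-parallel edges collapse with weights summed.
        Self-loops are dropped with a warning. Endpoints must be known
        nodes.
        """
        node_set = {str(v) for v in nodes}
        collapsed: dict[tuple[str, str], float] = {}
        n_loops = 0
        for e in edges:
            if len(e) == 3:
                u, v, w = str(e[0]), str(e[1]), float(e[2])
            else:
                u, v = str(e[0]), str(e[1])
                w = 1.0
            if u == v:
                n_loops += 1
                continue
            for x in (u, v):
                if x not in node_set:
                    raise NetworkValidationError(
                        f"edge ({u!r}, {v!r}) references unknown node {x!r}"
                    )
            if not math.isfinite(w) or w < 0:
                raise NetworkValidationError(
                    f"edge ({u!r}, {v!r}) has invalid weight {w!r}"
                )
            key = (u, v) if u < v else (v, u)
            collapsed[key] = collapsed.get(key, 0.0) + w
        if n_loops:
            logger.warning("dropped %d self-loop(s) during normalization", n_loops)

        order = tuple(sorted(node_set))
        c = None
        if coords is not None:
            c = {}
            for v in order:
                if v not in coords:
                    raise NetworkValidationError(f"node {v!r} has no coordinates")
                x, y = coords[v]
                if not (math.isfinite(x) and math.isfinite(y)):
                    raise NetworkValidationError(f"non-finite coordinates for {v!r}")
                c[v] = (float(x), float(y))
        lab = {str(k): str(s) for k, s in labels.items()} if labels else None
        return cls(order, collapsed, c, lab)

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    def index(self, node: str) -> int:
        return self._index[node]

    def adjacency(self) -> dict[str, dict[str, float]]:
        """Neighbor map ``{u: {v: weight}}`` (cached)."""
        if self._adj is None:
            adj: dict[str, dict[str, float]] = {v: {} for v in self.nodes}
            for (u, v), w in self.edges.items():
                adj[u][v] = w
                adj[v][u] = w
            self._adj = adj
        return self._adj

    def degrees(self, weighted: bool = True) -> dict[str, float]:
        deg = {v: 0.0 for v in self.nodes}
        for (u, v), w in self.edges.items():
            x = w if weighted else 1.0
            deg[u] += x
            deg[v] += x
        return deg

    def total_weight(self) -> float:
        return sum(self.edges.values())

    def has_unit_weights(self) -> bool:
        return all(w == 1.0 for w in self.edges.values())

    # ------------------------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, weight=w)
        if self.coords:
            for v, (x, y) in self.coords.items():
                g.nodes[v]["x"] = x
                g.nodes[v]["y"] = y
        if self.labels:
            for v, s in self.labels.items():
                g.nodes[v]["label"] = s
        return g

    @classmethod
    def from_networkx(cls, g) -> "Network":
        """Convert any networkx graph (directed graphs are symmetrized)."""
        edges = [(u, v, d.get("weight", 1.0)) for u, v, d in g.edges(data=True)]
        coords = None
        if g.number_of_nodes() and all(
            "x" in d and "y" in d for _, d in g.nodes(data=True)
        ):
            coords = {
                str(v): (float(d["x"]), float(d["y"])) for v, d in g.nodes(data=True)
            }
        labels = {
            str(v): str(d["label"]) for v, d in g.nodes(data=True) if "label" in d
        } or None
        return cls.build(map(str, g.nodes), edges, coords, labels)

    # ------------------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.coords == other.coords
        )

    def __repr__(self) -> str:
        return f"Network(n={self.n}, m={self.m}, coords={self.coords is not None})"
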