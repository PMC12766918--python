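"""Significance filtering and domain labelling.

A *domain* is a cluster with at least one significantly overrepresented
term; its display label is its best term. ``unique_clusters`` implements
the shared-node filter: nodes claimed by two or more significant clusters
are removed, and a cluster counts as unique if enough of its own nodes
survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotation import AnnotationMatrix
from .clustering import Partition

__all__ = ["DomainMap", "build_domains", "unique_clusters"]


@dataclass
class DomainMap:
    """Significant clusters with ranked term labels.

    ``labels`` holds, per significant cluster, the top terms as
    ``(term_id, p)`` pairs sorted ascending by p (ties by term id);
    ``significant_terms`` holds ALL terms below alpha per cluster.
    """

    significant_clusters: set[int]
    labels: dict[int, list[tuple[str, float]]]
    alpha: float
    significant_terms: dict[int, list[tuple[str, float]]] = field(default_factory=dict)

    def best_label(self, cluster_id: int, term_names=None) -> str:
        term, _ = self.labels[cluster_id][0]
        if term_names and term in term_names:
            return term_names[term]
        return term


def build_domains(
    tab: pd.DataFrame, alpha: float = 0.01, top_k: int = 3, use_adjusted: bool = True
) -> DomainMap:
    """Retain clusters with at least one term below ``alpha`` and rank
    their terms.

    ``use_adjusted`` selects the ``adj_p`` column (equal to the raw p when
    the table was built with ``correction='none'``).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if len(tab) == 0:
        raise ValueError("empty overrepresentation table")
    col = "adj_p" if use_adjusted else "p"
    sig = tab[tab[col] < alpha]
    clusters: set[int] = set()
    labels: dict[int, list[tuple[str, float]]] = {}
    all_terms: dict[int, list[tuple[str, float]]] = {}
    for cid, grp in sig.groupby("cluster"):
        cid = int(cid)
        ranked = sorted(zip(grp["term"], grp[col]), key=lambda t: (t[1], t[0]))
        clusters.add(cid)
        labels[cid] = ranked[:top_k]
        all_terms[cid] = ranked
    return DomainMap(
        significant_clusters=clusters,
        labels=labels,
        alpha=alpha,
        significant_terms=all_terms,
    )


def unique_clusters(
    dm: DomainMap,
    part: Partition,
    matrix: AnnotationMatrix | None = None,
    mode: str = "terms",
    min_remaining: int = 1,
) -> set[int]:
    """Significant clusters that survive removal of shared nodes.

    mode='terms' (default): each significant cluster's claimed node set is
    the union of its significant terms' members (requires ``matrix``);
    nodes claimed by >= 2 clusters are removed from every claim, and a
    cluster is unique if >= ``min_remaining`` nodes survive. Since hard
    partitions are disjoint, term-member claims are where overlap can
    actually arise. mode='partition' uses the partition's own node sets
    (useful for externally supplied overlapping cluster files).
    """
    if not dm.significant_clusters:
        raise ValueError("no significant clusters")
    if mode == "terms":
        if matrix is None:
            raise ValueError("mode='terms' requires the annotation matrix")
        claims = {
            cid: set().union(
                *(set(matrix.members(t)) for t, _ in dm.significant_terms[cid])
            )
            for cid in dm.significant_clusters
        }
    elif mode == "partition":
        groups = part.clusters()
        claims = {cid: set(groups[cid]) for cid in dm.significant_clusters}
    else:
        raise ValueError(f"unknown mode {mode!r}")

    counts: dict[str, int] = {}
    for nodes in claims.values():
        for v in nodes:
            counts[v] = counts.get(v, 0) + 1
    shared = {v for v, c in counts.items() if c >= 2}
    return {
        cid for cid, nodes in claims.items() if len(nodes - shared) >= min_remaining
    }
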