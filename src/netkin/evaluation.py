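"""Layout-based clustering quality metrics and partition comparison.

All metrics operate on 2-D layout coordinates:

* compactness — per cluster, the mean pairwise Euclidean distance among
  its nodes (singleton clusters are 0 by convention);
* separation — the minimum Euclidean distance between cluster centroids;
* silhouette — per node, s = (b - a) / max(a, b) with a the mean distance
  to the node's own cluster (excluding itself) and b the smallest mean
  distance to another cluster; singletons and coincident clusters score 0.

Two clusterings of the same layout are compared with a Mann-Whitney U
test on their per-cluster compactness distributions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy import stats as sps

from .clustering import Partition

__all__ = [
    "EvaluationReport",
    "compactness",
    "separation",
    "silhouette",
    "mann_whitney_u",
    "compare_partitions",
    "adjusted_rand_index",
]


@dataclass
class EvaluationReport:
    per_cluster_compactness: dict[int, float]
    separation: float
    silhouette_mean: float
    silhouette_per_node: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "per_cluster_compactness": {
                str(k): v for k, v in self.per_cluster_compactness.items()
            },
            "separation": self.separation,
            "silhouette_mean": self.silhouette_mean,
            "silhouette_per_node": self.silhouette_per_node,
        }


def _coord_arrays(coords: dict, part: Partition):
    nodes = sorted(part.assignment)
    missing = [v for v in nodes if v not in coords]
    if missing:
        raise ValueError(f"missing coordinates for nodes: {missing[:5]}")
    X = np.array([coords[v] for v in nodes], dtype=float)
    labels = np.array([part.assignment[v] for v in nodes])
    return nodes, X, labels


def compactness(coords: dict, part: Partition) -> dict[int, float]:
    """Mean pairwise Euclidean distance within each cluster."""
    _, X, labels = _coord_arrays(coords, part)
    out = {}
    for c in range(part.k):
        P = X[labels == c]
        if len(P) < 2:
            out[c] = 0.0
            continue
        D = cdist(P, P)
        n = len(P)
        out[c] = float(D[np.triu_indices(n, k=1)].mean())
    return out


def separation(coords: dict, part: Partition) -> float:
    """Minimum Euclidean distance between cluster centroids."""
    if part.k < 2:
        raise ValueError("separation requires >= 2 clusters")
    _, X, labels = _coord_arrays(coords, part)
    centroids = np.array([X[labels == c].mean(axis=0) for c in range(part.k)])
    D = cdist(centroids, centroids)
    return float(D[np.triu_indices(part.k, k=1)].min())


def silhouette(coords: dict, part: Partition):
    """Mean and per-node silhouette scores.

    Convention: nodes in singleton clusters, and nodes with a = b = 0,
    score 0.
    """
    if part.k < 2:
        raise ValueError("silhouette requires >= 2 clusters")
    nodes, X, labels = _coord_arrays(coords, part)
    D = cdist(X, X)
    sizes = np.bincount(labels, minlength=part.k)
    # mean distance from each node to each cluster
    sums = np.zeros((len(nodes), part.k))
    for c in range(part.k):
        sums[:, c] = D[:, labels == c].sum(axis=1)
    per_node = {}
    vals = []
    for i in range(len(nodes)):
        c = labels[i]
        if sizes[c] == 1:
            s = 0.0
        else:
            a = sums[i, c] / (sizes[c] - 1)
            b = min(
                sums[i, o] / sizes[o] for o in range(part.k) if o != c and sizes[o] > 0
            )
            s = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
        per_node[nodes[i]] = float(s)
        vals.append(s)
    return float(np.mean(vals)), per_node


# ----------------------------------------------------------------------
# Mann-Whitney U


def mann_whitney_u(x, y, alternative: str = "two-sided"):
    """Mann-Whitney U test.

    Exact p by enumeration of all rank assignments when |x| + |y| <= 12
    and there are no ties; otherwise the normal approximation with the
    standard tie-corrected variance and a 0.5 continuity correction.
    Returns (U, p) with U the statistic of the x sample
    (#{(i, j): x_i > y_j} + half-ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    nx, ny = len(x), len(y)
    diff = x[:, None] - y[None, :]
    U = float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if nx + ny <= 12 and not has_ties:
        # enumerate all ways the combined ranks split between the samples
        ranks = np.argsort(np.argsort(combined))  # 0-based ranks, no ties
        u_values = []
        for idx in itertools.combinations(range(nx + ny), nx):
            rx = ranks[list(idx)]
            u_values.append(rx.sum() - nx * (nx - 1) / 2)
        u_values = np.array(u_values)
        p_less = float((u_values <= U).mean())
        p_greater = float((u_values >= U).mean())
    else:
        mu = nx * ny / 2.0
        n = nx + ny
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        var = nx * ny / 12.0 * (n + 1 - tie_term)
        if var == 0:
            p_less = p_greater = 1.0
        else:
            sd = math.sqrt(var)
            p_less = float(sps.norm.cdf((U - mu + 0.5) / sd))
            p_greater = float(sps.norm.sf((U - mu - 0.5) / sd))
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return U, p


def compare_partitions(coords: dict, part_a: Partition, part_b: Partition):
    """Evaluate two partitions of the same layout.

    Returns ``(report_a, report_b, (U, p))`` where the Mann-Whitney U
    test compares the per-cluster compactness distributions.
    """
    if set(part_a.assignment) != set(part_b.assignment):
        raise ValueError("partitions cover different node sets")
    missing = [v for v in part_a.assignment if v not in coords]
    if missing:
        raise ValueError(f"missing coordinates for nodes: {missing[:5]}")

    reports = []
    for part in (part_a, part_b):
        comp = compactness(coords, part)
        sep = separation(coords, part) if part.k >= 2 else 0.0
        if part.k >= 2:
            sil_mean, sil_nodes = silhouette(coords, part)
        else:
            sil_mean, sil_nodes = 0.0, {v: 0.0 for v in part.assignment}
        reports.append(
            EvaluationReport(
                per_cluster_compactness=comp,
                separation=sep,
                silhouette_mean=sil_mean,
                silhouette_per_node=sil_nodes,
            )
        )
    mwu = mann_whitney_u(
        list(reports[0].per_cluster_compactness.values()),
        list(reports[1].per_cluster_compactness.values()),
        alternative="two-sided",
    )
    return reports[0], reports[1], mwu


def adjusted_rand_index(part_a: Partition, part_b: Partition) -> float:
    """ARI between two partitions of the same node set."""
    from sklearn.metrics import adjusted_rand_score

    nodes = sorted(part_a.assignment)
    if set(part_b.assignment) != set(nodes):
        raise ValueError("partitions cover different node sets")
    return float(
        adjusted_rand_score(
            [part_a.assignment[v] for v in nodes],
            [part_b.assignment[v] for v in nodes],
        )
    )
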