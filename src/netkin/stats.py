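"""Overrepresentation statistics on the sparse membership matrix.

For a cluster of size n in a universe of N nodes, of which K carry a term,
the observed overlap k is tested for enrichment with one of four tests:

* ``hypergeom``  — exact upper tail P(X >= k), X ~ Hypergeom(N, K, n)
* ``binom``      — upper tail of Binomial(n, K/N) at k
* ``chisq``      — one-sided 2x2 Pearson chi-squared (1 df, no continuity
  correction); enrichment p is half the chi-squared upper tail when
  a*d > b*c and 1 otherwise, so the direction always matches the other
  tests
* ``permutation``— node-label shuffle of the annotation rows; the add-one
  Monte-Carlo estimator p = (1 + #{k_r >= k_obs}) / (1 + R)

All tests are evaluated for every (cluster, term) pair in one vectorized
pass over sparse matrices; the permutation pass costs O(R * nnz) and never
materializes a dense N x T x R array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotationMatrix
from .clustering import Partition

__all__ = [
    "CountTable",
    "count_table",
    "count_matrix",
    "hypergeom_p",
    "binomial_p",
    "chisq_p",
    "permutation_p",
    "permutation_pass",
    "run_overrep",
    "ImpossibleTableError",
]

TESTS = ("permutation", "hypergeom", "chisq", "binom")


class ImpossibleTableError(ValueError):
    pass


@dataclass(frozen=True)
class CountTable:
    """Counts behind one (cluster, term) 2x2 table.

    k: annotated nodes inside the cluster; n: cluster size; K: annotated
    nodes in the universe; N: universe size. The 2x2 cells are
    a=k, b=n-k, c=K-k, d=N-n-K+k.
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self):
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"invalid counts: {self}")
        if self.n > self.N or self.K > self.N or self.N - self.n - self.K + self.k < 0:
            raise ValueError(f"invalid counts: {self}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (
            self.k,
            self.n - self.k,
            self.K - self.k,
            self.N - self.n - self.K + self.k,
        )


# ----------------------------------------------------------------------
# counting


def _universe_views(matrix: AnnotationMatrix, part: Partition):
    """Rows/labels restricted to the statistical universe."""
    mask = matrix.universe_mask
    sub = matrix.matrix[mask].tocsc()
    labels = part.labels_for(matrix.node_ids)[mask]
    return sub, labels


def count_matrix(matrix: AnnotationMatrix, part: Partition):
    """Vectorized counts for all pairs.

    Returns ``(k_mat, n_vec, K_vec, N)`` with ``k_mat`` a dense
    (clusters x terms) int array: k_mat = C @ M for the sparse cluster
    indicator C and membership matrix M.
    """
    sub, labels = _universe_views(matrix, part)
    n_univ = sub.shape[0]
    C = sp.csr_matrix(
        (np.ones(n_univ, dtype=np.int64), (labels, np.arange(n_univ))),
        shape=(part.k, n_univ),
    )
    k_mat = np.asarray((C @ sub).todense(), dtype=np.int64)
    n_vec = np.asarray(C.sum(axis=1)).ravel().astype(np.int64)
    K_vec = np.asarray(sub.sum(axis=0)).ravel().astype(np.int64)
    return k_mat, n_vec, K_vec, n_univ


def count_table(
    matrix: AnnotationMatrix, part: Partition, cluster_id: int, term_id: str
) -> CountTable:
    """Exact counts for a single (cluster, term) pair."""
    if not (0 <= cluster_id < part.k):
        raise KeyError(f"unknown cluster id {cluster_id}")
    j = matrix.term_index(term_id)
    sub, labels = _universe_views(matrix, part)
    col = np.asarray(sub[:, j].todense()).ravel()
    in_cluster = labels == cluster_id
    return CountTable(
        k=int(col[in_cluster].sum()),
        n=int(in_cluster.sum()),
        K=int(col.sum()),
        N=sub.shape[0],
    )


# ----------------------------------------------------------------------
# analytic tests


def hypergeom_p(ct: CountTable) -> float:
    """Upper-tail hypergeometric p = P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(sps.hypergeom.sf(ct.k - 1, ct.N, ct.K, ct.n))


def binomial_p(ct: CountTable) -> float:
    """Upper tail of Binomial(n, K/N) at k."""
    if ct.K == 0:
        if ct.k > 0:
            raise ImpossibleTableError(f"k={ct.k} > 0 with K=0")
        return 1.0
    return float(sps.binom.sf(ct.k - 1, ct.n, ct.K / ct.N))


def chisq_statistic(ct: CountTable) -> float:
    """Pearson chi-squared statistic, 1 df, no continuity correction:
    N (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]."""
    a, b, c, d = ct.cells
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return ct.N * (a * d - b * c) ** 2 / denom


def chisq_p(ct: CountTable) -> tuple[float, float]:
    """(statistic, one-sided enrichment p).

    Enrichment p is half the chi-squared(1) upper tail when a*d > b*c
    (the one-sided z test on the 2x2 table) and 1.0 otherwise, so the
    reported direction agrees with the exact tests. Degenerate tables
    (a zero margin) give (0, 1)."""
    a, b, c, d = ct.cells
    stat = chisq_statistic(ct)
    if a * d > b * c:
        return stat, float(sps.chi2.sf(stat, 1) / 2.0)
    return stat, 1.0


def _vector_p(test: str, k_mat, n_vec, K_vec, N, depletion: bool):
    """Dense (clusters x terms) p-values for an analytic test."""
    n_col = n_vec[:, None]
    K_row = K_vec[None, :]
    if test == "hypergeom":
        if depletion:
            return sps.hypergeom.cdf(k_mat, N, K_row, n_col)
        return sps.hypergeom.sf(k_mat - 1, N, K_row, n_col)
    if test == "binom":
        rate = K_row / N
        if depletion:
            return sps.binom.cdf(k_mat, n_col, rate)
        return sps.binom.sf(k_mat - 1, n_col, rate)
    if test == "chisq":
        a = k_mat
        b = n_col - k_mat
        c = K_row - k_mat
        d = N - n_col - K_row + k_mat
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(denom > 0, N * (a * d - b * c) ** 2.0 / denom, 0.0)
        tail = sps.chi2.sf(stat, 1) / 2.0
        assoc = (a * d < b * c) if depletion else (a * d > b * c)
        return np.where(assoc, tail, 1.0)
    raise ValueError(f"unknown analytic test {test!r}")


# ----------------------------------------------------------------------
# permutation test


def permutation_pass(
    matrix: AnnotationMatrix,
    part: Partition,
    R: int = 1000,
    seed: int = 0,
    null_model: str = "node-label-shuffle",
    depletion: bool = False,
):
    """One vectorized permutation pass for ALL (cluster, term) pairs.

    The null uniformly permutes the node rows of the annotation matrix
    (preserving term sizes and cluster sizes). Returns the add-one
    Monte-Carlo p matrix (clusters x terms); cost O(R * (N + nnz)).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if null_model != "node-label-shuffle":
        raise ValueError(f"unknown null model {null_model!r}")
    k_obs, n_vec, K_vec, N = count_matrix(matrix, part)
    sub, labels = _universe_views(matrix, part)
    coo = sub.tocoo()
    rows, cols = coo.row, coo.col
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(k_obs)
    counts = np.empty_like(k_obs)
    for _ in range(R):
        perm = rng.permutation(N)
        inv = np.empty(N, dtype=np.int64)
        inv[perm] = np.arange(N)
        # permuted matrix M'[i] = M[perm[i]]; entry (j, t) lands in the
        # cluster of the node that now holds row j
        counts[:] = 0
        np.add.at(counts, (labels[inv[rows]], cols), 1)
        if depletion:
            exceed += counts <= k_obs
        else:
            exceed += counts >= k_obs
    return (1.0 + exceed) / (1.0 + R)


def permutation_p(
    matrix: AnnotationMatrix,
    part: Partition,
    cluster_id: int,
    term_id: str,
    R: int = 1000,
    seed: int = 0,
    null_model: str = "node-label-shuffle",
) -> float:
    """Permutation p for a single pair (computed by the vectorized pass)."""
    p = permutation_pass(matrix, part, R=R, seed=seed, null_model=null_model)
    return float(p[cluster_id, matrix.term_index(term_id)])


# ----------------------------------------------------------------------
# full table


def run_overrep(
    matrix: AnnotationMatrix,
    part: Partition,
    test: str = "hypergeom",
    alpha: float = 0.05,
    correction: str = "bh",
    R: int = 1000,
    seed: int = 0,
    depletion: bool = False,
) -> pd.DataFrame:
    """Overrepresentation table for every (cluster, term) pair.

    Columns: cluster, term, k, n, K, N, p, adj_p, significant, test,
    direction. ``adj_p`` applies the chosen correction across ALL pairs;
    with ``correction='none'`` the raw p is used for the significance
    flag (the convention behind raw P < .01 thresholds).
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if correction not in ("bh", "bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")

    k_mat, n_vec, K_vec, N = count_matrix(matrix, part)
    if test == "permutation":
        p_mat = permutation_pass(
            matrix, part, R=R, seed=seed, depletion=depletion
        )
    else:
        p_mat = np.clip(
            _vector_p(test, k_mat, n_vec, K_vec, N, depletion), 0.0, 1.0
        )
        p_mat = np.where(p_mat <= 0, np.finfo(float).tiny, p_mat)

    k_clusters, n_terms = k_mat.shape
    cl = np.repeat(np.arange(k_clusters), n_terms)
    tm = np.tile(np.arange(n_terms), k_clusters)
    p = p_mat.ravel()
    if correction == "bh":
        adj = multipletests(p, method="fdr_bh")[1]
    elif correction == "bonferroni":
        adj = np.minimum(1.0, p * p.size)
    else:
        adj = p.copy()
    adj = np.maximum(adj, p)  # corrections never report below the raw p
    signif = adj < alpha

    return pd.DataFrame(
        {
            "cluster": cl,
            "term": np.asarray(matrix.term_ids, dtype=object)[tm],
            "k": k_mat.ravel(),
            "n": n_vec[cl],
            "K": K_vec[tm],
            "N": N,
            "p": p,
            "adj_p": adj,
            "significant": signif,
            "test": test,
            "direction": "depletion" if depletion else "enrichment",
        }
    )
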