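"""Overrepresentation tests against enumeration oracles and each other."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import netkin as nk
from netkin.stats import chisq_statistic, count_matrix


def enum_hypergeom(k, n, K, N):
    """P(|draw ∩ term| >= k) by enumerating all C(N, n) draws."""
    term = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        hits += len(term & set(draw)) >= k
    return hits / total


# ----------------------------------------------------------------------
# counting


def _small_fixture():
    net = nk.Network.build("ABCD", [("A", "B"), ("C", "D")])
    matrix = nk.build_matrix({"T1": ["B", "C"], "T2": ["A", "B", "C", "D"]},
                             net, min_size=1)
    part = nk.Partition.from_labels("ABCD", [0, 0, 1, 1])
    return net, matrix, part


def test_count_table_intersection():
    _, matrix, part = _small_fixture()
    ct = nk.count_table(matrix, part, 0, "T1")
    assert (ct.k, ct.n, ct.K, ct.N) == (1, 2, 2, 4)


def test_count_table_whole_universe_term():
    _, matrix, part = _small_fixture()
    ct = nk.count_table(matrix, part, 0, "T2")
    assert ct.k == ct.n == 2


def test_count_table_empty_intersection():
    net = nk.Network.build("ABCD", [("A", "B"), ("C", "D")])
    matrix = nk.build_matrix({"T1": ["C", "D"]}, net, min_size=1)
    part = nk.Partition.from_labels("ABCD", [0, 0, 1, 1])
    assert nk.count_table(matrix, part, 0, "T1").k == 0


def test_count_table_unknown_ids():
    _, matrix, part = _small_fixture()
    with pytest.raises(KeyError):
        nk.count_table(matrix, part, 9, "T1")
    with pytest.raises(KeyError):
        nk.count_table(matrix, part, 0, "nope")


def test_count_matrix_agrees_with_per_pair_tables(planted_fixture):
    _, truth, matrix = planted_fixture
    k_mat, n_vec, K_vec, N = count_matrix(matrix, truth)
    for cid in (0, 2):
        for term in ("signal_1", "decoy_03"):
            ct = nk.count_table(matrix, truth, cid, term)
            j = matrix.term_index(term)
            assert (k_mat[cid, j], n_vec[cid], K_vec[j], N) == (
                ct.k, ct.n, ct.K, ct.N
            )


# ----------------------------------------------------------------------
# analytic tests vs hand values and enumeration


def test_hypergeom_hand_values():
    assert nk.hypergeom_p(nk.CountTable(5, 5, 5, 10)) == pytest.approx(1 / 252)
    assert nk.hypergeom_p(nk.CountTable(0, 3, 4, 10)) == 1.0
    assert nk.hypergeom_p(nk.CountTable(1, 2, 2, 4)) == pytest.approx(5 / 6)


def test_hypergeom_matches_enumeration_spot():
    for k, n, K, N in [(2, 3, 4, 8), (1, 4, 2, 9), (3, 5, 5, 11)]:
        assert nk.hypergeom_p(nk.CountTable(k, n, K, N)) == pytest.approx(
            enum_hypergeom(k, n, K, N)
        )


def test_binomial_hand_values():
    assert nk.binomial_p(nk.CountTable(2, 2, 5, 10)) == pytest.approx(0.25)
    assert nk.binomial_p(nk.CountTable(0, 3, 5, 10)) == 1.0
    assert nk.binomial_p(nk.CountTable(2, 3, 4, 12)) == pytest.approx(7 / 27)


def test_binomial_impossible_table():
    with pytest.raises(ValueError):
        nk.CountTable(1, 2, 0, 4)  # k > K is itself invalid
    assert nk.binomial_p(nk.CountTable(0, 2, 0, 4)) == 1.0


def test_chisq_hand_values():
    stat, p = nk.chisq_p(nk.CountTable(10, 20, 20, 40))  # a=b=c=d=10
    assert stat == 0.0 and p == 1.0
    stat, p = nk.chisq_p(nk.CountTable(20, 25, 25, 50))  # a=20 b=5 c=5 d=20
    assert stat == pytest.approx(18.0)
    assert 0 < p < 0.5


def test_chisq_statistic_expected_count_oracle():
    """Closed form equals sum (O-E)^2/E over the 2x2 cells."""
    for cells in [(20, 5, 5, 20), (3, 7, 9, 31), (12, 4, 2, 2)]:
        a, b, c, d = cells
        N = a + b + c + d
        ct = nk.CountTable(a, a + b, a + c, N)
        obs = np.array([[a, b], [c, d]], dtype=float)
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        exp = row @ col / N
        assert chisq_statistic(ct) == pytest.approx(((obs - exp) ** 2 / exp).sum())


def test_chisq_symmetric_in_rows_and_columns():
    ct = nk.CountTable(12, 16, 20, 40)  # a=12 b=4 c=8 d=16
    a, b, c, d = ct.cells
    transposed = nk.CountTable(a, a + c, a + b, ct.N)
    assert chisq_statistic(ct) == pytest.approx(chisq_statistic(transposed))


def test_chisq_degenerate_margin():
    stat, p = nk.chisq_p(nk.CountTable(0, 0, 3, 10))  # empty cluster margin
    assert (stat, p) == (0.0, 1.0)


def test_all_tests_agree_on_enrichment_direction():
    """a*d > b*c is algebraically equivalent to k > nK/N (observed above
    expectation). All tests then point toward enrichment: the chi-squared
    p is < 0.5 outright, and the exact tests' STRICT tails P(X > k) are
    < 0.5 (their closed upper tails include the point mass at k, which
    can exceed 0.5 just above the mean — an unavoidable discreteness
    effect)."""
    from scipy import stats as sps

    rng = np.random.default_rng(0)
    checked = 0
    while checked < 1000:
        N = int(rng.integers(50, 200))
        n = int(rng.integers(5, N - 5))
        K = int(rng.integers(5, N - 5))
        k = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
        ct = nk.CountTable(k, n, K, N)
        a, b, c, d = ct.cells
        if a * d <= b * c or 0 in (a + b, c + d, a + c, b + d):
            continue
        checked += 1
        assert a * d > b * c and k * N > n * K  # the equivalence itself
        assert nk.hypergeom_p(ct) - sps.hypergeom.pmf(k, N, K, n) < 0.5
        assert nk.binomial_p(ct) - sps.binom.pmf(k, n, K / N) < 0.5
        assert nk.chisq_p(ct)[1] < 0.5


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.data())
def test_hypergeom_monotone_nonincreasing_in_k(data):
    N = data.draw(st.integers(4, 60))
    n = data.draw(st.integers(1, N - 1))
    K = data.draw(st.integers(1, N - 1))
    ps = [
        nk.hypergeom_p(nk.CountTable(k, n, K, N))
        for k in range(max(0, n + K - N), min(n, K) + 1)
    ]
    assert all(x >= y - 1e-12 for x, y in zip(ps, ps[1:]))


# ----------------------------------------------------------------------
# permutation test


def test_permutation_p_is_one_for_universal_term():
    net = nk.Network.build("ABCD", [("A", "B"), ("C", "D")])
    matrix = nk.build_matrix({"T": ["A", "B", "C", "D"]}, net, min_size=1)
    part = nk.Partition.from_labels("ABCD", [0, 0, 1, 1])
    assert nk.permutation_p(matrix, part, 0, "T", R=100, seed=0) == 1.0


def test_permutation_p_is_one_for_whole_network_cluster():
    net = nk.Network.build("ABCD", [("A", "B"), ("C", "D")])
    matrix = nk.build_matrix({"T": ["A", "B"]}, net, min_size=1)
    part = nk.Partition.from_labels("ABCD", [0, 0, 0, 0])
    assert nk.permutation_p(matrix, part, 0, "T", R=100, seed=0) == 1.0


def test_permutation_requires_positive_R(planted_fixture):
    _, truth, matrix = planted_fixture
    with pytest.raises(ValueError):
        nk.permutation_pass(matrix, truth, R=0)


def test_permutation_converges_to_hypergeometric():
    """Node-label shuffling has an exactly hypergeometric null, so the
    add-one Monte-Carlo estimate lands within 3 SE of its expectation."""
    R = 10_000
    net, truth, matrix = nk.gen_planted(4, 25, 0.5, 0.02, seed=2,
                                        coherent_terms=True)
    pm = nk.permutation_pass(matrix, truth, R=R, seed=5)
    k_mat, n_vec, K_vec, N = count_matrix(matrix, truth)
    from scipy import stats as sps

    hp = sps.hypergeom.sf(k_mat - 1, N, K_vec[None, :], n_vec[:, None])
    # compare the pair whose exact p is nearest 0.25 (meaningful SE)
    i, j = np.unravel_index(np.argmin(np.abs(hp - 0.25)), hp.shape)
    center = (1 + R * hp[i, j]) / (1 + R)
    se = math.sqrt(R * hp[i, j] * (1 - hp[i, j])) / (1 + R)
    assert abs(pm[i, j] - center) <= 3 * se


def naive_permutation(matrix, part, R, seed):
    """Per-pair loop over dense permuted matrices (oracle)."""
    M = np.asarray(matrix.matrix.todense())
    labels = part.labels_for(matrix.node_ids)
    N = M.shape[0]
    k_obs = np.array(
        [[M[labels == c][:, t].sum() for t in range(M.shape[1])]
         for c in range(part.k)]
    )
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(k_obs)
    for _ in range(R):
        perm = rng.permutation(N)
        Mp = M[perm]
        for c in range(part.k):
            sub = Mp[labels == c]
            for t in range(M.shape[1]):
                exceed[c, t] += sub[:, t].sum() >= k_obs[c, t]
    return (1.0 + exceed) / (1.0 + R)


def test_vectorized_permutation_equals_naive_loop_bit_exact():
    rng = np.random.default_rng(7)
    net = nk.gen_scale_free(30, 2, seed=7)
    mapping = {
        f"T{j}": [net.nodes[i] for i in rng.choice(30, 6, replace=False)]
        for j in range(10)
    }
    matrix = nk.build_matrix(mapping, net, min_size=1)
    part = nk.louvain(net, seed=7)
    fast = nk.permutation_pass(matrix, part, R=150, seed=42)
    slow = naive_permutation(matrix, part, R=150, seed=42)
    assert np.array_equal(fast, slow)


# ----------------------------------------------------------------------
# run_overrep


def test_run_overrep_bonferroni_definition(planted_fixture):
    _, truth, matrix = planted_fixture
    tab = nk.run_overrep(matrix, truth, test="hypergeom", correction="bonferroni")
    expected = np.minimum(1.0, tab["p"] * len(tab))
    assert np.allclose(tab["adj_p"], np.maximum(expected, tab["p"]))


def test_run_overrep_planted_term_has_minimum_p(planted_fixture):
    _, truth, matrix = planted_fixture
    tab = nk.run_overrep(matrix, truth, test="hypergeom", correction="none")
    best = tab.sort_values("p").iloc[0]
    assert str(best["term"]).startswith("signal_")


def test_adj_p_never_below_raw_p(planted_fixture):
    _, truth, matrix = planted_fixture
    for corr in ("bh", "bonferroni", "none"):
        tab = nk.run_overrep(matrix, truth, correction=corr)
        assert (tab["adj_p"] >= tab["p"] - 1e-15).all()


def test_run_overrep_depletion_direction(planted_fixture):
    _, truth, matrix = planted_fixture
    tab = nk.run_overrep(matrix, truth, test="hypergeom", depletion=True)
    assert (tab["direction"] == "depletion").all()
    # a signal term is depleted in the OTHER blocks
    row = tab[(tab.cluster == 1) & (tab.term == "signal_0")].iloc[0]
    assert row["p"] < 0.5


def test_run_overrep_argument_validation(planted_fixture):
    _, truth, matrix = planted_fixture
    with pytest.raises(ValueError):
        nk.run_overrep(matrix, truth, test="tea-leaves")
    with pytest.raises(ValueError):
        nk.run_overrep(matrix, truth, alpha=1.5)
    with pytest.raises(ValueError):
        nk.run_overrep(matrix, truth, correction="fdr_by_vibes")
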