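"""Graph metrics against brute-force oracles and analytic limits."""

import itertools

import networkx as nx
import numpy as np
import pytest

from tractnet import (
    clustering,
    find_modules,
    global_efficiency,
    local_efficiency,
    modularity_q,
    path_length,
    random_reference,
    small_worldness,
)
from conftest import random_weighted_graph


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation)


def brute_clustering(W, scaled=True):
    n = len(W)
    w = W / W.max() if scaled else W
    c = np.zeros(n)
    for i in range(n):
        k = np.count_nonzero(W[i])
        if k < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                acc += (w[i, j] * w[i, h] * w[j, h]) ** (1 / 3)
        c[i] = acc / (k * (k - 1))
    return c, c.mean()


def brute_geodesic(W, i, j):
    """Minimum sum of 1/w arc lengths over all simple paths (exhaustive)."""
    n = len(W)
    best = np.inf
    for r in range(n):
        for mid in itertools.permutations([x for x in range(n) if x not in (i, j)], r):
            path = (i, *mid, j)
            length = 0.0
            ok = True
            for a, b in zip(path[:-1], path[1:]):
                if W[a, b] == 0:
                    ok = False
                    break
                length += 1.0 / W[a, b]
            if ok:
                best = min(best, length)
    return best


def brute_global_efficiency(W):
    n = len(W)
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                d = brute_geodesic(W, i, j)
                acc += 0.0 if np.isinf(d) else 1.0 / d
    return acc / (n * (n - 1))


def all_partitions(nodes):
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in all_partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [[first] + block] + part[i + 1 :]
        yield [[first]] + part


def brute_best_partition(W):
    n = len(W)
    best_q, best_labels = -np.inf, None
    for part in all_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, block in enumerate(part):
            labels[block] = c
        q = modularity_q(W, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_labels, best_q


# ---------------------------------------------------------------------------
# analytic limits


def test_equal_weight_triangle_clusters_perfectly():
    W = np.array([[0, 2.0, 2.0], [2.0, 0, 2.0], [2.0, 2.0, 0]])
    c, mean_c = clustering(W)
    np.testing.assert_allclose(c, 1.0)
    assert mean_c == pytest.approx(1.0)


def test_star_graph_has_zero_clustering(rng):
    W = np.zeros((5, 5))
    W[0, 1:] = W[1:, 0] = rng.random(4) + 0.5
    assert clustering(W)[1] == pytest.approx(0.0)


def test_two_node_path_length_is_inverse_weight():
    W = np.array([[0.0, 10.0], [10.0, 0.0]])
    _, L = path_length(W)
    assert L == pytest.approx(0.1)
    assert global_efficiency(W) == pytest.approx(1.0 / L)


def test_unweighted_four_cycle_path_length():
    W = np.zeros((4, 4))
    for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
        W[i, j] = W[j, i] = 1.0
    assert path_length(W)[1] == pytest.approx(4 / 3)


def test_weak_edge_bypassed_by_strong_two_hop_route():
    # triangle with w = (10, 10, 1): the weak pair is closer via two hops
    W = np.array([[0, 10.0, 1.0], [10.0, 0, 10.0], [1.0, 10.0, 0]])
    D, _ = path_length(W)
    assert D[0, 2] == pytest.approx(0.2)
    assert D[0, 2] == pytest.approx(brute_geodesic(W, 0, 2))


def test_complete_unweighted_graph_efficiencies_are_one():
    W = 1.0 - np.eye(6)
    assert global_efficiency(W) == pytest.approx(1.0)
    assert local_efficiency(W) == pytest.approx(1.0)


def test_isolated_nodes_have_zero_efficiency():
    assert global_efficiency(np.zeros((2, 2))) == pytest.approx(0.0)


def test_tree_has_zero_local_efficiency(rng):
    W = np.zeros((6, 6))
    for child, parent in enumerate([0, 0, 1, 1, 2], start=1):
        W[child, parent] = W[parent, child] = rng.random() + 0.5
    assert local_efficiency(W) == pytest.approx(0.0)


def test_disconnected_network_rejected_for_path_length():
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1.0
    with pytest.raises(ValueError, match="disconnected"):
        path_length(W)


def test_two_cliques_natural_partition_q_half():
    W = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for i, j in itertools.combinations(block, 2):
            W[i, j] = W[j, i] = 1.0
    labels = [0] * 4 + [1] * 4
    assert modularity_q(W, labels) == pytest.approx(0.5)
    assert modularity_q(W, [0] * 8) == pytest.approx(0.0)


def test_random_partition_has_zero_mean_modularity(rng):
    # E[Q] = -k var(a_c) under uniform random k-partitions: ~0 for large n
    n = 80
    W = random_weighted_graph(n, 0.3, rng)
    qs = [modularity_q(W, rng.integers(0, 3, size=n)) for _ in range(300)]
    assert abs(np.mean(qs)) < 0.02


# ---------------------------------------------------------------------------
# brute-force equivalence on small random graphs


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("scaled", [True, False])
def test_clustering_matches_exhaustive_triples(seed, scaled):
    rng = np.random.default_rng(seed)
    W = random_weighted_graph(6, 0.6, rng)
    c, mean_c = clustering(W, scaled=scaled)
    c_ref, mean_ref = brute_clustering(W, scaled=scaled)
    np.testing.assert_allclose(c, c_ref, atol=1e-12)
    assert mean_c == pytest.approx(mean_ref)


@pytest.mark.parametrize("seed", [3, 4])
def test_geodesics_match_exhaustive_path_enumeration(seed):
    rng = np.random.default_rng(seed)
    W = random_weighted_graph(5, 0.7, rng)
    D, _ = path_length(W)
    for i in range(5):
        for j in range(5):
            if i != j:
                assert D[i, j] == pytest.approx(brute_geodesic(W, i, j))


def test_efficiencies_match_brute_force(rng):
    W = random_weighted_graph(5, 0.7, rng)
    assert global_efficiency(W) == pytest.approx(brute_global_efficiency(W))
    n = len(W)
    acc = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(W[i])
        if len(nbrs) >= 2:
            acc += brute_global_efficiency(W[np.ix_(nbrs, nbrs)])
    assert local_efficiency(W) == pytest.approx(acc / n)


def test_spectral_modules_match_exhaustive_search():
    # two 4-cliques joined by one negligible-weight edge
    W = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for i, j in itertools.combinations(block, 2):
            W[i, j] = W[j, i] = 1.0
    W[3, 4] = W[4, 3] = 1e-3
    part = find_modules(W)
    labels_ref, q_ref = brute_best_partition(W)
    assert part.q == pytest.approx(q_ref, abs=1e-9)
    # same split up to relabeling
    assert len(set(zip(part.labels, labels_ref))) == len(set(labels_ref))


def test_modularity_agrees_with_networkx(rng):
    W = random_weighted_graph(12, 0.4, rng)
    part = find_modules(W)
    G = nx.from_numpy_array(W)
    comms = [set(np.flatnonzero(part.labels == c)) for c in np.unique(part.labels)]
    q_nx = nx.community.modularity(G, comms, weight="weight")
    assert part.q == pytest.approx(q_nx, abs=1e-9)


def test_clustering_agrees_with_networkx(rng):
    W = random_weighted_graph(10, 0.5, rng)
    c, _ = clustering(W, scaled=True)
    c_nx = nx.clustering(nx.from_numpy_array(W), weight="weight")
    np.testing.assert_allclose(c, [c_nx[i] for i in range(10)], atol=1e-9)


def test_planted_modules_recovered(rng):
    # 3 blocks of 6, dense within, sparse weak between
    n, k = 18, 3
    labels_true = np.repeat(np.arange(k), n // k)
    W = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        if labels_true[i] == labels_true[j]:
            W[i, j] = W[j, i] = 1.0 + rng.random()
        elif rng.random() < 0.1:
            W[i, j] = W[j, i] = 0.05
    part = find_modules(W)
    pairs = set(zip(part.labels, labels_true))
    assert len(pairs) == k  # one-to-one up to relabeling


# ---------------------------------------------------------------------------
# null model and small-worldness


def test_random_reference_invariants(rng):
    W = random_weighted_graph(20, 0.3, rng)
    R = random_reference(W, n_swaps=100, seed=1)
    np.testing.assert_array_equal((R > 0).sum(axis=1), (W > 0).sum(axis=1))
    np.testing.assert_allclose(
        np.sort(R[np.triu_indices(20, 1)]), np.sort(W[np.triu_indices(20, 1)])
    )
    np.testing.assert_array_equal(random_reference(W, 0, seed=1), W)


def test_star_graph_swaps_impossible(rng):
    W = np.zeros((5, 5))
    W[0, 1:] = W[1:, 0] = 1.0
    with pytest.warns(UserWarning, match="no degree-preserving swap"):
        R = random_reference(W, n_swaps=10, seed=0)
    np.testing.assert_array_equal(R, W)


def test_self_referenced_null_gives_unit_small_worldness(rng):
    W = random_weighted_graph(12, 0.5, rng)
    gamma, lam, sigma = small_worldness(W, ensemble_size=3, n_swaps=0, seed=0)
    assert (gamma, lam, sigma) == (1.0, 1.0, 1.0)


def test_sigma_is_exactly_gamma_over_lambda(rng):
    W = random_weighted_graph(16, 0.4, rng)
    gamma, lam, sigma = small_worldness(W, ensemble_size=4, seed=3)
    assert sigma == gamma / lam


def test_modular_networks_are_small_world(default_cohort):
    from tractnet import extract_backbone

    hits = 0
    for sample in default_cohort[:4]:
        bb = extract_backbone(sample.networks[0])
        _, _, sigma = small_worldness(bb, ensemble_size=10, seed=11)
        hits += sigma > 1
    assert hits == 4


class TestMetricProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(seed=st.integers(0, 2**16))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_scaled_clustering_in_unit_interval_and_q_bounded(self, seed):
        rng = np.random.default_rng(seed)
        W = random_weighted_graph(9, 0.5, rng, connected=False)
        if W.max() == 0:
            return
        c, mean_c = clustering(W, scaled=True)
        assert np.all((c >= -1e-12) & (c <= 1 + 1e-12))
        assert 0.0 <= mean_c <= 1.0
        from tractnet import find_modules

        if (W.sum(axis=1) > 0).all():
            part = find_modules(W)
            assert part.q <= 1.0

    @given(seed=st.integers(0, 2**16))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_scaled_clustering_reduces_to_unweighted_on_equal_weights(self, seed):
        rng = np.random.default_rng(seed)
        A = (random_weighted_graph(8, 0.5, rng, connected=False) > 0).astype(float)
        c, _ = clustering(A * 3.7, scaled=True)
        c_nx = nx.clustering(nx.from_numpy_array(A))
        np.testing.assert_allclose(c, [c_nx[i] for i in range(8)], atol=1e-9)


def test_global_efficiency_monotone_under_edge_removal(rng):
    W = random_weighted_graph(8, 0.6, rng)
    e_full = global_efficiency(W)
    iu, ju = np.nonzero(np.triu(W, 1))
    for i, j in zip(iu[:5], ju[:5]):
        W2 = W.copy()
        W2[i, j] = W2[j, i] = 0.0
        assert global_efficiency(W2) <= e_full + 1e-12
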