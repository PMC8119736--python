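"""Graph metrics against independent brute-force oracles, surrogate
invariants, sparsity sweep contracts."""

import itertools
import logging

import networkx as nx
import numpy as np
import pytest

from nirsnet.connectivity import ConnectivityMatrix
from nirsnet.graphmetrics import (
    BinaryNetwork,
    GraphMetricError,
    central_nodes,
    characteristic_path_length,
    clustering_coefficient,
    compute_metrics,
    double_edge_swap,
    global_efficiency,
    local_efficiency,
    matched_random_ensemble,
    modularity,
    modularity_value,
    normalized_metrics,
    sparsity_sweep,
    sweep_grid,
    threshold_by_sparsity,
)

# --- independent oracles ------------------------------------------------


def brute_clustering(adj):
    n = len(adj)
    total = 0.0
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        d = len(nb)
        if d < 2:
            continue
        links = sum(adj[a][b] for a, b in itertools.combinations(nb, 2))
        total += links / (d * (d - 1) / 2)
    return total / n


def brute_distances(adj):
    n = len(adj)
    d = [[0 if i == j else (1 if adj[i][j] else np.inf) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return np.array(d)


def brute_path_length(adj):
    d = brute_distances(adj)
    vals = d[np.triu_indices(len(adj), 1)]
    return vals[np.isfinite(vals)].mean()


def brute_global_eff(adj):
    n = len(adj)
    d = brute_distances(adj)
    total = sum(
        1.0 / d[i][j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i][j])
    )
    return total / (n * (n - 1))


def brute_local_eff(adj):
    n = len(adj)
    total = 0.0
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        if len(nb) < 2:
            continue
        sub = [[adj[a][b] for b in nb] for a in nb]
        total += brute_global_eff(sub)
    return total / n


def _net(adj, s=0.5):
    return BinaryNetwork(labels=[f"n{i}" for i in range(len(adj))], adjacency=np.array(adj), sparsity=s)


def _random_net(rng, n_min=4, n_max=10):
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = rng.uniform(0.2, 0.9)
        a = (rng.random((n, n)) < p).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        if a.sum() >= 2:
            return _net(a)


# --- thresholding -------------------------------------------------------


def _conn(values, labels=None):
    n = len(values)
    labels = labels or [f"n{i}" for i in range(n)]
    return ConnectivityMatrix(labels=labels, values=np.asarray(values, float), kind="fisher_z", chromophore="HbR")


def test_45_nodes_at_030_gives_297_edges(rng):
    v = rng.standard_normal((45, 45))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    net = threshold_by_sparsity(_conn(v), 0.30)
    assert net.n_edges == round(0.30 * 990) == 297


def test_toy_matrix_keeps_three_largest_edges():
    v = np.zeros((4, 4))
    pairs = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.1, (1, 2): 0.7, (1, 3): 0.2, (2, 3): 0.3}
    for (i, j), val in pairs.items():
        v[i, j] = v[j, i] = val
    net = threshold_by_sparsity(_conn(v), 0.5)
    assert net.n_edges == 3
    assert set(net.edges()) == {(0, 1), (0, 2), (1, 2)}


def test_near_unit_sparsity_gives_complete_graph():
    v = np.random.default_rng(0).standard_normal((5, 5))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    net = threshold_by_sparsity(_conn(v), 0.999)
    assert net.n_edges == 10


def test_tie_break_is_lexicographic():
    v = np.full((4, 4), 0.5)
    np.fill_diagonal(v, 0.0)
    net = threshold_by_sparsity(_conn(v), 0.34)  # keeps round(0.34*6)=2 of 6 tied pairs
    assert net.edges() == [(0, 1), (0, 2)]


def test_zero_edge_sparsity_rejected():
    v = np.zeros((4, 4))
    with pytest.raises(GraphMetricError, match="zero"):
        threshold_by_sparsity(_conn(v), 0.01)


# --- metric oracles -----------------------------------------------------


def test_complete_graph_metrics():
    k5 = 1 - np.eye(5, dtype=int)
    net = _net(k5)
    assert clustering_coefficient(net) == pytest.approx(1.0)
    assert characteristic_path_length(net) == pytest.approx(1.0)
    assert global_efficiency(net) == pytest.approx(1.0)
    assert local_efficiency(net) == pytest.approx(1.0)


def test_star_graph_has_zero_clustering():
    a = np.zeros((6, 6), int)
    a[0, 1:] = a[1:, 0] = 1
    assert clustering_coefficient(_net(a)) == 0.0


def test_path_graph_characteristic_length():
    a = np.zeros((3, 3), int)
    a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
    assert characteristic_path_length(_net(a)) == pytest.approx(4.0 / 3.0)


def test_ring_lattice_matches_floyd_warshall():
    g = nx.cycle_graph(10)
    a = nx.to_numpy_array(g, dtype=int)
    assert characteristic_path_length(_net(a)) == pytest.approx(brute_path_length(a))


def test_disconnected_pairs_warned_and_excluded(caplog):
    a = np.zeros((4, 4), int)
    a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
    with caplog.at_level(logging.WARNING, logger="nirsnet.graphmetrics"):
        lp = characteristic_path_length(_net(a))
    assert lp == pytest.approx(1.0)  # two connected pairs, both at distance 1
    assert "disconnected" in caplog.text


def test_edgeless_graph_path_length_errors():
    with pytest.raises(GraphMetricError, match="no connected"):
        characteristic_path_length(_net(np.zeros((3, 3), int)))


def test_two_cliques_modularity_half():
    a = np.zeros((8, 8), int)
    a[:4, :4] = 1 - np.eye(4)
    a[4:, 4:] = 1 - np.eye(4)
    net = _net(a)
    q = modularity_value(net, [{0, 1, 2, 3}, {4, 5, 6, 7}])
    assert q == pytest.approx(0.5)
    q_best, part = modularity(net, n_restarts=5, seed=0)
    assert q_best == pytest.approx(0.5)
    assert {frozenset(p) for p in part} == {frozenset(range(4)), frozenset(range(4, 8))}


def test_complete_graph_single_module_q_zero():
    k5 = 1 - np.eye(5, dtype=int)
    assert modularity_value(_net(k5), [set(range(5))]) == pytest.approx(0.0)


def test_modularity_value_matches_networkx(rng):
    for _ in range(20):
        net = _random_net(rng)
        n = net.n_nodes
        sizes = rng.integers(1, n + 1)
        labels = rng.integers(0, max(int(sizes), 1), size=n)
        part = [set(np.flatnonzero(labels == k)) for k in np.unique(labels)]
        g = nx.from_numpy_array(net.adjacency)
        expected = nx.community.modularity(g, [list(p) for p in part])
        assert modularity_value(net, part) == pytest.approx(expected, abs=1e-12)


def test_heuristic_q_at_least_trivial_partition(rng):
    for _ in range(10):
        net = _random_net(rng)
        q, _ = modularity(net, n_restarts=3, seed=1)
        assert q >= modularity_value(net, [set(range(net.n_nodes))]) - 1e-12


def test_two_isolated_cliques_efficiency_below_one():
    a = np.zeros((8, 8), int)
    a[:4, :4] = 1 - np.eye(4)
    a[4:, 4:] = 1 - np.eye(4)
    assert global_efficiency(_net(a)) == pytest.approx(3.0 / 7.0)  # 3 reachable of 7 others


def test_oracle_equivalence_on_random_small_graphs(rng):
    """Clustering, path length and both efficiencies agree with independent
    brute-force enumeration on random graphs with up to 10 nodes."""
    for _ in range(60):
        net = _random_net(rng)
        a = net.adjacency.tolist()
        assert clustering_coefficient(net) == pytest.approx(brute_clustering(a), abs=1e-12)
        assert global_efficiency(net) == pytest.approx(brute_global_eff(a), abs=1e-12)
        assert local_efficiency(net) == pytest.approx(brute_local_eff(a), abs=1e-12)
        assert characteristic_path_length(net) == pytest.approx(brute_path_length(a), abs=1e-12)


# --- surrogates ---------------------------------------------------------


def test_surrogates_preserve_degree_sequence(rng):
    g = nx.watts_strogatz_graph(30, 6, 0.2, seed=5)
    net = _net(nx.to_numpy_array(g, dtype=int))
    for k in range(10):
        surrogate, n_swaps = double_edge_swap(net, np.random.default_rng(k))
        assert np.array_equal(surrogate.degrees, net.degrees)
        assert surrogate.n_edges == net.n_edges
        assert n_swaps > 0


def test_complete_graph_surrogates_identical():
    k6 = 1 - np.eye(6, dtype=int)
    net = _net(k6)
    with pytest.warns(UserWarning, match="no valid"):
        stats = matched_random_ensemble(net, count=5, seed=0)
    assert stats.cp_mean == pytest.approx(1.0)
    assert stats.lp_mean == pytest.approx(1.0)


def test_small_world_rewiring_lowers_clustering(rng):
    g = nx.watts_strogatz_graph(45, 6, 0.1, seed=2)
    net = _net(nx.to_numpy_array(g, dtype=int))
    cp_real = clustering_coefficient(net)
    lower = 0
    for k in range(10):
        stats = matched_random_ensemble(net, count=5, seed=k)
        lower += stats.cp_mean < cp_real
    assert lower >= 9


def test_ensemble_reproducible_under_seed():
    g = nx.watts_strogatz_graph(20, 4, 0.2, seed=3)
    net = _net(nx.to_numpy_array(g, dtype=int))
    a = matched_random_ensemble(net, count=8, seed=42)
    b = matched_random_ensemble(net, count=8, seed=42)
    assert a == b


# --- normalization and sweep --------------------------------------------


def test_complete_graph_normalized_ratios_unity():
    k6 = 1 - np.eye(6, dtype=int)
    net = _net(k6)
    with pytest.warns(UserWarning):
        stats = matched_random_ensemble(net, count=3, seed=0)
    m = normalized_metrics(net, stats)
    assert m.cp_gamma == pytest.approx(1.0)
    assert m.lp_lambda == pytest.approx(1.0)
    assert m.sigma == pytest.approx(1.0)
    assert m.eloc_gamma == pytest.approx(1.0)
    assert m.eglob_gamma == pytest.approx(1.0)


def test_sigma_is_ratio_of_gammas(rng):
    net = _random_net(rng, n_min=8, n_max=10)
    m = compute_metrics(net, ensemble_count=5, seed=1)
    assert m.sigma == pytest.approx(m.cp_gamma / m.lp_lambda)


def test_default_grid_has_36_thresholds():
    grid = sweep_grid()
    assert len(grid) == 36
    assert grid[0] == pytest.approx(0.05)
    assert grid[-1] == pytest.approx(0.40)


def test_sweep_edge_count_monotone(rng):
    v = rng.standard_normal((45, 45))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    mat = _conn(v)
    metrics = sparsity_sweep(mat, ensemble_count=0, seed=0)
    assert len(metrics) == 36
    edge_counts = [m.degree.sum() // 2 for m in metrics]
    assert all(b >= a for a, b in zip(edge_counts, edge_counts[1:]))
    assert all(np.isnan(m.sigma) for m in metrics)  # no ensemble -> no ratios


def test_degree_sums_to_twice_edges(rng):
    for _ in range(20):
        net = _random_net(rng)
        assert net.degrees.sum() == 2 * net.n_edges


# --- central nodes ------------------------------------------------------


def test_regular_graph_has_no_hubs():
    g = nx.cycle_graph(10)
    net = _net(nx.to_numpy_array(g, dtype=int))
    hubs = central_nodes({"control": [net]})
    assert hubs == {"control": []}


def test_star_cohort_hub_is_center():
    a = np.zeros((6, 6), int)
    a[0, 1:] = a[1:, 0] = 1
    net = _net(a)
    hubs = central_nodes({"patient": [net, net]})
    assert hubs == {"patient": ["n0"]}
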