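"""Strength, shortest paths, centralities, clustering, and hub detection."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import dijkstra

from empathnet import (
    betweenness_centrality,
    centrality_table,
    closeness_centrality,
    clustering_coefficient,
    detect_hubs,
    edge_lengths,
    node_strength,
    shortest_paths,
)
from empathnet.metrics import hub_rank_cutoff

from conftest import random_weight_matrix, triangle_pair_weights


def _edge(n, pairs):
    w = np.zeros((n, n))
    for a, b, v in pairs:
        w[a, b] = w[b, a] = v
    return w


def test_node_strength_examples_and_oracle():
    w = _edge(4, [(0, 1, 0.5)])
    assert np.allclose(node_strength(w), [0.5, 0.5, 0.0, 0.0])
    assert np.allclose(node_strength(np.zeros((3, 3))), 0.0)
    rng = np.random.default_rng(0)
    w = random_weight_matrix(rng, 10)
    expected = [sum(abs(w[i, j]) for j in range(10)) for i in range(10)]
    assert np.allclose(node_strength(w), expected)


def test_edge_lengths_reciprocal():
    w = _edge(3, [(0, 1, 0.5), (1, 2, 1.0)])
    lengths = edge_lengths(w)
    assert lengths[0, 1] == 2.0 and lengths[1, 2] == 1.0
    assert np.isinf(lengths[0, 2]) and lengths[0, 0] == 0.0
    rng = np.random.default_rng(1)
    w = random_weight_matrix(rng, 8)
    lengths = edge_lengths(w)
    for i in range(8):
        for j in range(8):
            if i == j:
                assert lengths[i, j] == 0.0
            elif w[i, j] > 0:
                assert lengths[i, j] == pytest.approx(1.0 / w[i, j])
            else:
                assert np.isinf(lengths[i, j])


def test_shortest_paths_small_examples():
    w = _edge(3, [(0, 1, 1.0), (1, 2, 1.0)])
    sp = shortest_paths(edge_lengths(w))
    assert sp.distances[0, 2] == pytest.approx(2.0)
    assert sp.path(0, 2) == [0, 1, 2]
    # disconnected pair
    w = _edge(4, [(0, 1, 1.0), (2, 3, 1.0)])
    sp = shortest_paths(edge_lengths(w))
    assert np.isinf(sp.distances[0, 2]) and sp.path(0, 2) is None
    with pytest.raises(ValueError):
        shortest_paths(np.array([[0.0, -1.0], [-1.0, 0.0]]))


def test_shortest_paths_match_dijkstra_per_source():
    rng = np.random.default_rng(2)
    for _ in range(10):
        n = int(rng.integers(4, 13))
        w = random_weight_matrix(rng, n, density=0.4)
        lengths = edge_lengths(w)
        sp = shortest_paths(lengths)
        finite = np.where(np.isfinite(lengths), lengths, 0.0)
        ref = dijkstra(finite, directed=False)
        assert np.allclose(sp.distances, ref)
        # reconstructed paths realize the reported distances
        for i in range(n):
            for j in range(n):
                path = sp.path(i, j)
                if path is None:
                    assert np.isinf(sp.distances[i, j])
                else:
                    total = sum(lengths[a, b] for a, b in zip(path, path[1:]))
                    assert total == pytest.approx(sp.distances[i, j])


def _betweenness_oracle(w):
    """Count geodesics through each node by exhaustive path enumeration."""
    n = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                g.add_edge(i, j, length=1.0 / w[i, j])
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t, weight="length"))
        for v in range(n):
            if v in (s, t):
                continue
            bc[v] += sum(v in p for p in paths) / len(paths)
    return bc


def test_betweenness_examples_and_oracle():
    path = _edge(3, [(0, 1, 1.0), (1, 2, 1.0)])
    assert np.allclose(betweenness_centrality(path), [0.0, 1.0, 0.0])
    star = _edge(5, [(0, i, 1.0) for i in range(1, 5)])
    assert betweenness_centrality(star)[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
    rng = np.random.default_rng(3)
    for _ in range(5):
        w = random_weight_matrix(rng, 9, density=0.45)
        assert np.allclose(betweenness_centrality(w), _betweenness_oracle(w), atol=1e-9)


def test_closeness_examples_and_oracle():
    path = _edge(3, [(0, 1, 1.0), (1, 2, 1.0)])
    cc = closeness_centrality(path)
    assert cc[1] == pytest.approx(1.0)
    assert cc[0] == pytest.approx(2.0 / 3.0)
    # isolated node
    w = _edge(3, [(0, 1, 1.0)])
    assert closeness_centrality(w)[2] == 0.0
    # connected graph: (n-1) / row sum of distances
    rng = np.random.default_rng(4)
    w = random_weight_matrix(rng, 8, density=0.9)
    sp = shortest_paths(edge_lengths(w))
    expected = (8 - 1) / sp.distances.sum(axis=1)
    assert np.allclose(closeness_centrality(w), expected)


def _clustering_oracle(w):
    n = w.shape[0]
    wh = w / w.max()
    c = np.zeros(n)
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    total += (wh[i, j] * wh[j, h] * wh[i, h]) ** (1.0 / 3.0)
        c[i] = total / (k * (k - 1))
    return c


def test_clustering_examples_and_oracle():
    tri = _edge(3, [(0, 1, 0.7), (1, 2, 0.7), (0, 2, 0.7)])
    assert np.allclose(clustering_coefficient(tri), 1.0)
    path = _edge(3, [(0, 1, 1.0), (1, 2, 1.0)])
    assert np.allclose(clustering_coefficient(path), 0.0)
    rng = np.random.default_rng(5)
    for _ in range(5):
        w = random_weight_matrix(rng, 8, density=0.5)
        assert np.allclose(clustering_coefficient(w), _clustering_oracle(w), atol=1e-12)


def test_clustering_matches_networkx_onnela():
    rng = np.random.default_rng(6)
    w = random_weight_matrix(rng, 10, density=0.5)
    g = nx.from_numpy_array(w)
    ref = nx.clustering(g, weight="weight")
    mine = clustering_coefficient(w)
    assert np.allclose(mine, [ref[i] for i in range(10)], atol=1e-12)


def test_hub_rank_cutoff():
    assert hub_rank_cutoff(24, 0.20) == 5
    assert hub_rank_cutoff(10, 0.20) == 2
    with pytest.raises(ValueError):
        hub_rank_cutoff(10, 0.0)


def test_detect_hubs_rules():
    # node 0: rank 1 everywhere -> hub; node 1: ranks 5, 6, 6 -> not a hub
    p = 24
    base = np.linspace(100, 1, p)
    table = pd.DataFrame({
        "node": [f"x{i}" for i in range(p)],
        "strength": base,
        "betweenness": np.roll(base, 1),
        "closeness": np.roll(base, 1),
        "clustering": np.ones(p),
    })
    table.loc[0, ["strength", "betweenness", "closeness"]] = [200, 200, 200]
    # between the 4th and 5th largest of the remaining values in each column:
    # rank 5 on strength (larger: 200, base[2..4]) but rank 6 on the rolled
    # columns (larger: 200, base[1..4])
    mid = (base[4] + base[5]) / 2
    table.loc[1, ["strength", "betweenness", "closeness"]] = [mid, mid, mid]
    from scipy.stats import rankdata

    for m in ("strength", "betweenness", "closeness"):
        table[f"rank_{m}"] = rankdata(-table[m].to_numpy(), method="min").astype(int)
    hubs = detect_hubs(table)
    assert "x0" in hubs
    assert table.loc[1, "rank_strength"] == 5
    assert "x1" not in hubs
    # brute-force counting oracle
    cutoff = hub_rank_cutoff(p, 0.20)
    expected = [
        row["node"]
        for _, row in table.iterrows()
        if sum(row[f"rank_{m}"] <= cutoff for m in ("strength", "betweenness", "closeness")) >= 2
    ]
    assert hubs == expected


def test_centrality_table_strength_invariant():
    rng = np.random.default_rng(7)
    w = random_weight_matrix(rng, 10, density=0.4)
    table = centrality_table(w)
    assert np.allclose(table["strength"], w.sum(axis=1))
    assert ((table["clustering"] >= 0) & (table["clustering"] <= 1.0 + 1e-12)).all()


def test_measures_equivariant_under_relabeling():
    rng = np.random.default_rng(8)
    w = random_weight_matrix(rng, 9, density=0.5)
    perm = rng.permutation(9)
    wp = w[np.ix_(perm, perm)]
    assert np.allclose(node_strength(wp), node_strength(w)[perm])
    assert np.allclose(betweenness_centrality(wp), betweenness_centrality(w)[perm], atol=1e-9)
    assert np.allclose(closeness_centrality(wp), closeness_centrality(w)[perm])
    assert np.allclose(clustering_coefficient(wp), clustering_coefficient(w)[perm])


def test_positive_rescaling_behaviour():
    rng = np.random.default_rng(9)
    w = random_weight_matrix(rng, 8, density=0.6)
    c = 3.7
    assert np.allclose(node_strength(c * w), c * node_strength(w))
    assert np.allclose(clustering_coefficient(c * w), clustering_coefficient(w))
    # orderings preserved for distance-based measures
    assert np.array_equal(
        np.argsort(betweenness_centrality(c * w)), np.argsort(betweenness_centrality(w))
    )
    assert np.array_equal(
        np.argsort(closeness_centrality(c * w)), np.argsort(closeness_centrality(w))
    )


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        node_strength(np.array([[0.0, -0.2], [-0.2, 0.0]]))
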