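"""Regional network measures on the absolute-weight undirected network.

Strength, betweenness and closeness centralities, the Onnela weighted
clustering coefficient, all-pairs shortest paths (Floyd-Warshall with a
canonical path reconstruction), and rank-based hub detection.

Distance-based measures use the length transform L_ij = 1 / w_ij, so stronger
edges are shorter. Betweenness follows the Brandes convention for undirected
graphs: unordered source-target pairs, endpoints excluded, no normalization.
Closeness uses the component-scaled convention
CC(v) = (r / (n-1)) * (r / sum of distances to the r reachable nodes),
which reduces to (n-1)/sum on a connected graph and to 0 for isolates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import floyd_warshall
from scipy.stats import rankdata

from .ising import IsingNetwork

logger = logging.getLogger(__name__)

DEFAULT_HUB_TOP_FRACTION = 0.20
DEFAULT_HUB_MIN_MEASURES = 2

_HUB_MEASURES = ("strength", "betweenness", "closeness")


def _weights(net) -> np.ndarray:
    w = net.weights if isinstance(net, IsingNetwork) else np.asarray(net, dtype=float)
    if np.any(w < 0):
        raise ValueError("expected an absolute-weight network (apply to_absolute_network first)")
    return w


def _labels(net, w) -> list[str]:
    if isinstance(net, IsingNetwork):
        return list(net.node_labels)
    return [f"node_{i}" for i in range(w.shape[0])]


def node_strength(net) -> np.ndarray:
    """Row sums of |W|: total absolute edge weight at each node."""
    return _weights(net).sum(axis=1)


def edge_lengths(net) -> np.ndarray:
    """Weight-to-length conversion: L_ij = 1/w_ij, inf for absent edges, 0 diagonal."""
    w = _weights(net)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


@dataclass(frozen=True)
class ShortestPathResult:
    """All-pairs distances plus a canonical next-hop matrix.

    ``next_hop[i, j]`` is the first intermediate node on the canonical
    shortest path from i to j (-1 when unreachable or i == j). Among equal
    geodesics the reconstruction greedily takes the lowest-index next hop,
    giving the lexicographically smallest node sequence.
    """

    distances: np.ndarray
    next_hop: np.ndarray

    def path(self, i: int, j: int) -> list[int] | None:
        """One canonical shortest node sequence from i to j, or None if unreachable."""
        if i == j:
            return [i]
        if not np.isfinite(self.distances[i, j]):
            return None
        seq = [i]
        cur = i
        while cur != j:
            cur = int(self.next_hop[cur, j])
            seq.append(cur)
        return seq


def shortest_paths(lengths: np.ndarray, rel_tol: float = 1e-10) -> ShortestPathResult:
    """All-pairs shortest paths on a nonnegative length matrix (Floyd-Warshall)."""
    L = np.asarray(lengths, dtype=float)
    if np.any(L[np.isfinite(L)] < 0):
        raise ValueError("negative edge length")
    D = floyd_warshall(L, directed=False)
    n = L.shape[0]
    next_hop = np.full((n, n), -1, dtype=int)
    # canonical next hop: smallest neighbour h of i with L[i,h] + D[h,j] == D[i,j]
    for i in range(n):
        nbrs = np.flatnonzero(np.isfinite(L[i]) & (np.arange(n) != i))
        for j in range(n):
            if i == j or not np.isfinite(D[i, j]):
                continue
            for h in nbrs:
                if abs(L[i, h] + D[h, j] - D[i, j]) <= rel_tol * max(1.0, D[i, j]):
                    next_hop[i, j] = h
                    break
    return ShortestPathResult(distances=D, next_hop=next_hop)


def _length_graph(net) -> nx.Graph:
    w = _weights(net)
    g = nx.Graph()
    g.add_nodes_from(range(w.shape[0]))
    for i in range(w.shape[0]):
        for j in range(i + 1, w.shape[0]):
            if w[i, j] > 0:
                g.add_edge(i, j, length=1.0 / w[i, j])
    return g


def betweenness_centrality(net) -> np.ndarray:
    """Unnormalized weighted betweenness (Brandes; unordered pairs, endpoints excluded)."""
    g = _length_graph(net)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(g.number_of_nodes())])


def closeness_centrality(net=None, distances: np.ndarray | None = None) -> np.ndarray:
    """Component-scaled closeness from the shortest-path distance matrix."""
    if distances is None:
        distances = shortest_paths(edge_lengths(net)).distances
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if n == 1:
        return np.zeros(1)
    out = np.zeros(n)
    for v in range(n):
        d = np.delete(D[v], v)
        reach = np.isfinite(d)
        r = int(reach.sum())
        total = float(d[reach].sum())
        if r == 0 or total == 0.0:
            continue
        out[v] = (r / (n - 1)) * (r / total)
    return out


def clustering_coefficient(net) -> np.ndarray:
    """Onnela weighted clustering: geometric-mean triangle intensity per node.

    With weights normalized by the network maximum, C_i = sum over neighbour
    pairs (j,k) of (w_ij w_jk w_ik)^(1/3) / (k_i (k_i - 1)); nodes with binary
    degree < 2 have C_i = 0.
    """
    w = _weights(net)
    if w.shape[0] == 0:
        return np.zeros(0)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0])
    w_hat = np.cbrt(w / wmax)
    cyc = np.diag(w_hat @ w_hat @ w_hat)  # 2 * sum of triangle intensities
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, cyc / denom, 0.0)
    return c


def centrality_table(
    net,
    top_fraction: float = DEFAULT_HUB_TOP_FRACTION,
    min_measures: int = DEFAULT_HUB_MIN_MEASURES,
) -> pd.DataFrame:
    """Per-node strength/betweenness/closeness/clustering, ranks, and hub flags.

    Ranks use competition ranking (1 = highest; ties share the best rank).
    """
    w = _weights(net)
    labels = _labels(net, w)
    lengths = edge_lengths(w)
    sp = shortest_paths(lengths)
    table = pd.DataFrame(
        {
            "node": labels,
            "strength": node_strength(w),
            "betweenness": betweenness_centrality(w),
            "closeness": closeness_centrality(distances=sp.distances),
            "clustering": clustering_coefficient(w),
        }
    )
    for m in _HUB_MEASURES:
        table[f"rank_{m}"] = rankdata(-table[m].to_numpy(), method="min").astype(int)
    cutoff = hub_rank_cutoff(len(labels), top_fraction)
    in_top = sum((table[f"rank_{m}"] <= cutoff).astype(int) for m in _HUB_MEASURES)
    table["is_hub"] = in_top >= min_measures
    return table


def hub_rank_cutoff(n_nodes: int, top_fraction: float = DEFAULT_HUB_TOP_FRACTION) -> int:
    """Rank cutoff r* = round(top_fraction * n_nodes), half away from zero."""
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    return int(np.floor(top_fraction * n_nodes + 0.5))


def detect_hubs(
    table: pd.DataFrame,
    top_fraction: float = DEFAULT_HUB_TOP_FRACTION,
    min_measures: int = DEFAULT_HUB_MIN_MEASURES,
) -> list[str]:
    """Nodes ranked <= r* in at least ``min_measures`` of strength,
    betweenness, closeness (clustering is never a hub criterion).

    With ties sharing the best rank, more than r* nodes can sit at rank <= r*;
    all tied nodes are included (a warning is logged).
    """
    cutoff = hub_rank_cutoff(len(table), top_fraction)
    counts = sum((table[f"rank_{m}"] <= cutoff).astype(int) for m in _HUB_MEASURES)
    hubs = table.loc[counts >= min_measures, "node"].tolist()
    for m in _HUB_MEASURES:
        if (table[f"rank_{m}"] <= cutoff).sum() > cutoff:
            logger.warning("ties push the top-%d set past the cutoff on %s; tied nodes included", cutoff, m)
            break
    return hubs
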