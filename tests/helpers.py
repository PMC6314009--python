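"""Shared test utilities: random graphs and brute-force bridge oracles.

The oracles deliberately avoid the package's Dijkstra-based code paths:
distances come from exhaustive simple-path enumeration so the two routes are
independent.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from symptomnet.graph import NetworkGraph


def random_weighted_graph(seed: int, p_min: int = 4, p_max: int = 7):
    """Random signed weighted graph with a random two-cluster split."""
    rng = np.random.default_rng(seed)
    p = int(rng.integers(p_min, p_max + 1))
    weights = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < 0.5:
                w = rng.uniform(0.2, 1.5) * (1 if rng.random() < 0.8 else -1)
                weights[i, j] = weights[j, i] = w
    labels = [f"n{i}" for i in range(p)]
    # random split with both sides nonempty
    while True:
        clusters = rng.integers(0, 2, size=p)
        if 0 < clusters.sum() < p:
            break
    return NetworkGraph(weights, labels), ["a" if c else "b" for c in clusters]


def _simple_path_distance(graph: NetworkGraph, s: int, t: int):
    """Shortest s-t distance on 1/|w| lengths by enumerating all simple paths.

    Returns (distance, list of minimal paths); (inf, []) when unreachable.
    """
    g = nx.Graph()
    g.add_nodes_from(range(graph.p))
    for i, j, w in graph.edges():
        g.add_edge(i, j, length=1.0 / abs(w))
    best = np.inf
    best_paths: list[list[int]] = []
    for path in nx.all_simple_paths(g, s, t):
        d = sum(g[a][b]["length"] for a, b in itertools.pairwise(path))
        if d < best - 1e-12:
            best = d
            best_paths = [path]
        elif abs(d - best) <= 1e-12:
            best_paths.append(path)
    return best, best_paths


def brute_bridge_strength(graph: NetworkGraph, clusters, v: int) -> float:
    arr = np.asarray(list(clusters))
    total = 0.0
    for u in range(graph.p):
        if arr[u] != arr[v]:
            total += abs(graph.weights[v, u])
    return total


def brute_bridge_betweenness(graph: NetworkGraph, clusters, v: int) -> int:
    arr = np.asarray(list(clusters))
    count = 0
    for s in range(graph.p):
        for t in range(s + 1, graph.p):
            if v in (s, t) or arr[s] == arr[t]:
                continue
            dist, paths = _simple_path_distance(graph, s, t)
            if not np.isfinite(dist):
                continue
            if any(v in path for path in paths):
                count += 1
    return count


def brute_bridge_closeness(graph: NetworkGraph, clusters, v: int) -> float:
    arr = np.asarray(list(clusters))
    total = 0.0
    for u in range(graph.p):
        if arr[u] == arr[v]:
            continue
        dist, _ = _simple_path_distance(graph, v, u)
        if not np.isfinite(dist):
            return 0.0
        total += dist
    return 1.0 / total
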