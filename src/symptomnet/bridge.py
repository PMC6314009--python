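"""Bridge centrality: strength, betweenness and closeness across clusters.

All three indices score how strongly a focal symptom connects to the nodes
outside its own cluster:

* bridge strength — sum of absolute edge weights to the other cluster(s);
* bridge betweenness — number of cross-cluster pairs whose shortest path
  passes through the focal node (edge length 1/|weight|); a pair counts once
  even if several shortest paths tie;
* bridge closeness — inverse of the summed shortest distance from the focal
  node to every node of the other cluster(s); 0 if any of them is
  unreachable.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError
from .graph import NetworkGraph

__all__ = [
    "bridge_strength",
    "bridge_betweenness",
    "bridge_closeness",
    "bridge_table",
]

_REL_TOL = 1e-9


def _clusters_array(graph: NetworkGraph, clusters) -> np.ndarray:
    if isinstance(clusters, Mapping):
        arr = np.array([clusters[l] for l in graph.labels])
    else:
        arr = np.asarray(list(clusters))
    if arr.size != graph.p:
        raise DataError("cluster assignment must cover every node")
    return arr


def _node_index(graph: NetworkGraph, node) -> int:
    if isinstance(node, str):
        return graph.labels.index(node)
    return int(node)


def _length_graph(graph: NetworkGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.p))
    for i, j, w in graph.edges():
        g.add_edge(i, j, length=1.0 / abs(w))
    return g


def _all_pairs_distances(graph: NetworkGraph) -> np.ndarray:
    g = _length_graph(graph)
    dist = np.full((graph.p, graph.p), np.inf)
    for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight="length"):
        for dst, d in lengths.items():
            dist[src, dst] = d
    return dist


def bridge_strength(graph: NetworkGraph, clusters, node) -> float:
    """Sum of absolute weights from ``node`` to every node in other clusters."""
    arr = _clusters_array(graph, clusters)
    v = _node_index(graph, node)
    other = arr != arr[v]
    return float(np.abs(graph.weights[v, other]).sum())


def bridge_betweenness(graph: NetworkGraph, clusters, node) -> int:
    """Count of cross-cluster pairs whose shortest path runs through ``node``."""
    arr = _clusters_array(graph, clusters)
    v = _node_index(graph, node)
    dist = _all_pairs_distances(graph)
    return _betweenness_from_distances(dist, arr, v)


def _betweenness_from_distances(dist: np.ndarray, arr: np.ndarray, v: int) -> int:
    p = dist.shape[0]
    count = 0
    for s in range(p):
        if s == v:
            continue
        for t in range(s + 1, p):
            if t == v or arr[s] == arr[t]:
                continue
            d_st = dist[s, t]
            if not math.isfinite(d_st):
                continue
            via = dist[s, v] + dist[v, t]
            if math.isfinite(via) and via <= d_st * (1.0 + _REL_TOL) + 1e-12:
                count += 1
    return count


def bridge_closeness(graph: NetworkGraph, clusters, node) -> float:
    """Inverse summed shortest distance from ``node`` to the other cluster(s)."""
    arr = _clusters_array(graph, clusters)
    v = _node_index(graph, node)
    dist = _all_pairs_distances(graph)
    return _closeness_from_distances(dist, arr, v)


def _closeness_from_distances(dist: np.ndarray, arr: np.ndarray, v: int) -> float:
    others = np.flatnonzero(arr != arr[v])
    if others.size == 0:
        raise DataError("bridge closeness needs at least one node in another cluster")
    d = dist[v, others]
    if not np.all(np.isfinite(d)):
        return 0.0
    return float(1.0 / d.sum())


def bridge_table(
    graph: NetworkGraph,
    clusters,
    endorsement_rates: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-symptom bridge indices as a table (one row per node).

    Columns: label, cluster, optional endorsement percentage, bridge
    strength, bridge betweenness, bridge closeness.
    """
    arr = _clusters_array(graph, clusters)
    dist = _all_pairs_distances(graph)
    rows = []
    for v, label in enumerate(graph.labels):
        other = arr != arr[v]
        row = {
            "label": label,
            "cluster": arr[v],
            "bridge_strength": float(np.abs(graph.weights[v, other]).sum()),
            "bridge_betweenness": _betweenness_from_distances(dist, arr, v),
            "bridge_closeness": _closeness_from_distances(dist, arr, v),
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    if endorsement_rates is not None:
        table.insert(2, "endorsement_pct", 100.0 * np.asarray(endorsement_rates, float))
    return table
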