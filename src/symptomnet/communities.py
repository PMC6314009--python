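"""Walktrap community detection on the estimated symptom network.

Edge weights enter the random walks as absolute values (association
strength); the dendrogram is cut at the level of maximal modularity. Nodes
without any incident edge stay singleton communities.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import igraph as ig
import numpy as np

from .errors import DataError
from .graph import NetworkGraph

__all__ = ["Partition", "walktrap", "modularity"]


@dataclasses.dataclass
class Partition:
    """Node-to-community assignment with the modularity of the chosen cut."""

    membership: dict[str, int]
    n_communities: int
    modularity: float
    merges: list[tuple[int, int]]

    def labels_for(self, labels) -> np.ndarray:
        return np.array([self.membership[str(l)] for l in labels])

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for label, cid in self.membership.items():
            out.setdefault(cid, []).append(label)
        return out

    def to_json(self) -> dict:
        return {
            "membership": self.membership,
            "n_communities": self.n_communities,
            "modularity": self.modularity,
            "merges": [list(m) for m in self.merges],
        }

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_json(), handle, indent=2)


def _canonical_membership(labels, raw: list[int]) -> tuple[dict[str, int], int]:
    """Renumber community ids contiguously from 0 in order of first appearance."""
    remap: dict[int, int] = {}
    membership = {}
    for label, cid in zip(labels, raw):
        if cid not in remap:
            remap[cid] = len(remap)
        membership[label] = remap[cid]
    return membership, len(remap)


def modularity(graph: NetworkGraph, membership) -> float:
    """Newman modularity on absolute weights.

    Q = sum_c (e_c / m - (d_c / 2m)^2) with e_c the within-community weight,
    d_c the summed weighted degree and m the total absolute weight.
    """
    if isinstance(membership, Partition):
        member = membership.labels_for(graph.labels)
    elif isinstance(membership, dict):
        member = np.array([membership[l] for l in graph.labels])
    else:
        member = np.asarray(membership)
    absw = graph.abs_weights()
    m = absw.sum() / 2.0
    if m == 0.0:
        raise DataError("modularity undefined on a graph with zero total weight")
    q = 0.0
    for c in np.unique(member):
        in_c = member == c
        e_c = absw[np.ix_(in_c, in_c)].sum() / 2.0
        d_c = absw[in_c].sum()
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def walktrap(graph: NetworkGraph, t: int = 4) -> Partition:
    """Walktrap partition of the network, cut at maximal modularity.

    Random-walk transition probabilities use absolute edge weights; the
    agglomerative merge sequence is returned as the dendrogram. A graph with
    no edges yields singleton communities with modularity 0 and a warning.
    """
    if graph.p == 0:
        raise DataError("walktrap needs a nonempty graph")
    edges = graph.edges()
    if not edges:
        warnings.warn(
            "graph has no edges; every node is its own community",
            RuntimeWarning,
            stacklevel=2,
        )
        membership = {label: i for i, label in enumerate(graph.labels)}
        return Partition(membership, graph.p, 0.0, [])

    degree = graph.abs_weights().sum(axis=0)
    connected = [i for i in range(graph.p) if degree[i] > 0.0]
    isolated = [i for i in range(graph.p) if degree[i] == 0.0]
    sub_index = {node: k for k, node in enumerate(connected)}

    g = ig.Graph(n=len(connected))
    g.add_edges([(sub_index[i], sub_index[j]) for i, j, _ in edges])
    g.es["weight"] = [abs(w) for _, _, w in edges]
    dendrogram = g.community_walktrap(weights="weight", steps=t)
    clustering = dendrogram.as_clustering()

    raw = [-1] * graph.p
    for node, cid in zip(connected, clustering.membership):
        raw[node] = int(cid)
    next_id = max(raw) + 1
    for node in isolated:
        raw[node] = next_id
        next_id += 1
    membership, n_comm = _canonical_membership(graph.labels, raw)

    # merge list in full-graph node indices; internal clusters get ids >= p
    merges = []
    offset = len(connected)
    for a, b in dendrogram.merges:
        left = connected[a] if a < offset else graph.p + (a - offset)
        right = connected[b] if b < offset else graph.p + (b - offset)
        merges.append((int(left), int(right)))

    return Partition(membership, n_comm, modularity(graph, membership), merges)
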