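"""Weighted undirected symptom network container and its serializations."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["NetworkGraph"]


@dataclasses.dataclass
class NetworkGraph:
    """Symmetric weighted adjacency with labeled nodes; weight != 0 means edge."""

    weights: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.labels = [str(l) for l in self.labels]
        p = len(self.labels)
        if self.weights.shape != (p, p):
            raise DataError("adjacency shape must match the number of labels")
        if not np.array_equal(self.weights, self.weights.T):
            raise DataError("adjacency must be exactly symmetric")
        if np.any(np.diag(self.weights) != 0.0):
            raise DataError("adjacency diagonal must be zero")
        if len(set(self.labels)) != p:
            raise DataError("node labels must be unique")

    @property
    def p(self) -> int:
        return len(self.labels)

    def edges(self) -> list[tuple[int, int, float]]:
        """Nonzero upper-triangle entries as (i, j, weight), i < j."""
        out = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.weights[i, j]
                if w != 0.0:
                    out.append((i, j, float(w)))
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edges())

    def abs_weights(self) -> np.ndarray:
        return np.abs(self.weights)

    def permuted(self, order: Sequence[int]) -> "NetworkGraph":
        """Relabeled copy with node ``order[k]`` placed at position k."""
        order = list(order)
        idx = np.asarray(order)
        return NetworkGraph(self.weights[np.ix_(idx, idx)], [self.labels[i] for i in order])

    # ---- serialization -------------------------------------------------

    def to_adjacency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.labels, columns=self.labels)

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {"node_i": self.labels[i], "node_j": self.labels[j], "weight": w}
            for i, j, w in self.edges()
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def write_adjacency_csv(self, path) -> None:
        self.to_adjacency_frame().to_csv(path, index_label="")

    def write_edge_csv(self, path) -> None:
        self.to_edge_frame().to_csv(path, index=False)

    def to_networkx(self, absolute: bool = False) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for i, j, w in self.edges():
            g.add_edge(self.labels[i], self.labels[j], weight=abs(w) if absolute else w)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def from_adjacency_frame(cls, frame: pd.DataFrame) -> "NetworkGraph":
        return cls(frame.to_numpy(dtype=float), [str(c) for c in frame.columns])

    @classmethod
    def read_adjacency_csv(cls, path) -> "NetworkGraph":
        frame = pd.read_csv(path, index_col=0)
        return cls.from_adjacency_frame(frame)

    @classmethod
    def from_edges(
        cls, labels: Sequence[str], edges: Sequence[tuple], directed_ok: bool = False
    ) -> "NetworkGraph":
        """Build from (i, j, weight) index triples or (label_i, label_j, weight)."""
        labels = [str(l) for l in labels]
        index = {l: k for k, l in enumerate(labels)}
        p = len(labels)
        w = np.zeros((p, p))
        for a, b, weight in edges:
            i = index[a] if isinstance(a, str) else int(a)
            j = index[b] if isinstance(b, str) else int(b)
            if i == j:
                raise DataError(f"self-edge at node {labels[i]!r}")
            w[i, j] = w[j, i] = float(weight)
        return cls(w, labels)
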