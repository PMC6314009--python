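"""Bootstrapped edge-weight accuracy: percentile CIs for every edge.

Rows are resampled with replacement B times; the full network estimator is
rerun on every resample. A node whose column loses all variance in a
resample has its edges recorded as 0 for that replicate; replicates with
fewer than two variable columns are fully degenerate and recorded as all
zeros, and more than 50% of those aborts the run.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .data_prep import SymptomData
from .elasso import EstimationConfig, estimate_network
from .errors import DataError, EstimationError
from .graph import NetworkGraph

__all__ = ["BootstrapSummary", "bootstrap_edges"]


@dataclasses.dataclass
class BootstrapSummary:
    """Replicate edge weights, percentile bounds and CI-overlap indicators."""

    labels: list[str]
    pairs: list[tuple[int, int]]  # all unordered node pairs, i < j
    estimates: np.ndarray  # (n_pairs,) point estimates
    replicates: np.ndarray  # (B, n_pairs); absent edge in a replicate = 0
    ci_low: np.ndarray
    ci_high: np.ndarray
    B: int
    seed: int | None
    n_degenerate: int

    def pair_labels(self) -> list[str]:
        return [f"{self.labels[i]}--{self.labels[j]}" for i, j in self.pairs]

    def overlap_matrix(self) -> np.ndarray:
        """overlap[a, b] iff CI_a and CI_b overlap: max(lower) <= min(upper)."""
        lo = self.ci_low
        hi = self.ci_high
        return (np.maximum.outer(lo, lo) <= np.minimum.outer(hi, hi))

    def to_frame(self, nonzero_only: bool = False) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "edge": self.pair_labels(),
                "estimate": self.estimates,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )
        if nonzero_only:
            frame = frame[frame["estimate"] != 0.0].reset_index(drop=True)
        return frame

    def write_csv(self, path, nonzero_only: bool = False) -> None:
        self.to_frame(nonzero_only).to_csv(path, index=False)

    def overlap_summary(self) -> dict:
        present = np.flatnonzero(self.estimates != 0.0)
        if present.size < 2:
            share = 1.0
        else:
            om = self.overlap_matrix()[np.ix_(present, present)]
            iu = np.triu_indices(present.size, k=1)
            share = float(om[iu].mean())
        return {
            "n_edges": int(present.size),
            "share_overlapping_ci_pairs": share,
            "B": self.B,
            "n_degenerate_replicates": self.n_degenerate,
        }

    def write_overlap_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.overlap_summary(), handle, indent=2)


def _replicate_weights(sub: np.ndarray, data: SymptomData, config: EstimationConfig) -> np.ndarray:
    """Estimate a network on one resample, padding degenerate nodes with 0."""
    p = sub.shape[1]
    rates = sub.mean(axis=0)
    keep = np.flatnonzero((rates > 0.0) & (rates < 1.0))
    weights = np.zeros((p, p))
    if keep.size >= 2:
        kept_data = SymptomData(
            sub[:, keep],
            [data.symptom_labels[j] for j in keep],
            [data.cluster_labels[j] for j in keep],
        )
        graph, _ = estimate_network(kept_data, config)
        weights[np.ix_(keep, keep)] = graph.weights
    return weights


def bootstrap_edges(
    data: SymptomData,
    config: EstimationConfig | None = None,
    B: int = 1000,
    seed: int | None = 0,
    point_graph: NetworkGraph | None = None,
    index_hook=None,
) -> BootstrapSummary:
    """Case-resampling bootstrap of every edge weight with 95% percentile CIs.

    ``index_hook(b, n, rng)`` may supply the row indices of replicate ``b``
    (test hook; e.g. the identity for zero-width CIs). All randomness comes
    from ``seed``.
    """
    if B < 2:
        raise DataError("bootstrap needs B >= 2 replicates")
    config = config or EstimationConfig()
    if point_graph is None:
        point_graph, _ = estimate_network(data, config)
    p = data.p
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    iu = np.triu_indices(p, k=1)
    estimates = point_graph.weights[iu]

    rng = np.random.default_rng(seed)
    replicates = np.zeros((B, len(pairs)))
    n_degenerate = 0
    for b in range(B):
        if index_hook is not None:
            idx = np.asarray(index_hook(b, data.n, rng))
        else:
            idx = rng.integers(0, data.n, size=data.n)
        sub = data.matrix[idx]
        rates = sub.mean(axis=0)
        if np.count_nonzero((rates > 0.0) & (rates < 1.0)) < 2:
            n_degenerate += 1
            if n_degenerate > B / 2:
                raise EstimationError(
                    f"more than half of the bootstrap resamples ({n_degenerate}"
                    f"/{b + 1} drawn) are degenerate; data too sparse to resample"
                )
            continue
        replicates[b] = _replicate_weights(sub, data, config)[iu]
    if n_degenerate > B / 2:
        raise EstimationError("more than half of the bootstrap resamples are degenerate")

    ci_low = np.percentile(replicates, 2.5, axis=0)
    ci_high = np.percentile(replicates, 97.5, axis=0)
    return BootstrapSummary(
        labels=list(data.symptom_labels),
        pairs=pairs,
        estimates=estimates,
        replicates=replicates,
        ci_low=ci_low,
        ci_high=ci_high,
        B=B,
        seed=seed,
        n_degenerate=n_degenerate,
    )
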