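"""Binary Ising distribution: exact enumeration, sampling, cohort generator.

The model over x in {0,1}^p is

    P(x) proportional to exp(sum_i tau_i x_i + sum_{i<j} omega_ij x_i x_j)

with node thresholds ``tau`` on the log-odds scale and a symmetric zero-
diagonal coupling matrix ``omega``. The same parameterization is what the
nodewise logistic regressions of :mod:`symptomnet.elasso` estimate, so the
generator doubles as ground truth for recovery experiments.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .errors import ConfigError, ConvergenceError, DataError, EstimationError

__all__ = [
    "IsingParameters",
    "GeneratorConfig",
    "StudyLikeTruth",
    "enumerate_pmf",
    "state_matrix",
    "marginals",
    "conditional_logit",
    "sample",
    "make_study_like",
    "generate_cohort",
]

#: Enumeration is limited to 2^21 states; beyond that use Gibbs sampling.
MAX_ENUMERATION_P = 21
#: Exact (inverse-CDF) sampling shares the enumeration limit: the 2^21
#: cumulative table costs ~16 MB, and iid draws avoid the slow phase mixing
#: a single Gibbs chain suffers on strongly coupled models.
MAX_EXACT_SAMPLING_P = 21


@dataclasses.dataclass(frozen=True)
class IsingParameters:
    """Node thresholds and symmetric couplings, both on the log-odds scale."""

    tau: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        omega = np.asarray(self.omega, dtype=float)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "omega", omega)
        if tau.ndim != 1:
            raise ConfigError("tau must be a vector")
        if omega.shape != (tau.size, tau.size):
            raise ConfigError("omega must be p x p")
        if not np.allclose(omega, omega.T):
            raise ConfigError("omega must be symmetric")
        if np.any(np.diag(omega) != 0.0):
            raise ConfigError("omega must have a zero diagonal")

    @property
    def p(self) -> int:
        return self.tau.size


def state_matrix(p: int) -> np.ndarray:
    """All 2^p binary states as a (2^p, p) uint8 matrix; row index = bit code."""
    states = np.arange(1 << p, dtype=np.uint32)
    return np.stack([(states >> i) & 1 for i in range(p)], axis=1).astype(np.uint8)


def _log_weights(params: IsingParameters) -> np.ndarray:
    p = params.p
    states = np.arange(1 << p, dtype=np.uint32)
    logw = np.zeros(states.size, dtype=float)
    bits = []
    for i in range(p):
        b = ((states >> i) & 1).astype(np.float64)
        bits.append(b)
        if params.tau[i] != 0.0:
            logw += params.tau[i] * b
    for i in range(p):
        for j in range(i + 1, p):
            w_ij = params.omega[i, j]
            if w_ij != 0.0:
                logw += w_ij * (bits[i] * bits[j])
    return logw


def enumerate_pmf(params: IsingParameters) -> np.ndarray:
    """Exact probability of every state; index s encodes x_i = bit i of s.

    Raises
    ------
    EstimationError
        If p exceeds the enumeration limit; use Gibbs sampling instead.
    """
    if params.p > MAX_ENUMERATION_P:
        raise EstimationError(
            f"enumeration over 2^{params.p} states is infeasible (limit "
            f"p <= {MAX_ENUMERATION_P}); use Gibbs sampling instead"
        )
    logw = _log_weights(params)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def marginals(params: IsingParameters) -> np.ndarray:
    """P(x_i = 1) for every node, from exact enumeration."""
    probs = enumerate_pmf(params)
    states = np.arange(probs.size, dtype=np.uint32)
    return np.array(
        [probs[((states >> i) & 1).astype(bool)].sum() for i in range(params.p)]
    )


def conditional_logit(params: IsingParameters, node: int) -> tuple[float, np.ndarray]:
    """Exact conditional of one node given the rest.

    P(x_i = 1 | x_{-i}) = logistic(tau_i + sum_{j != i} omega_ij x_j); the
    returned pair is (intercept tau_i, coefficient vector = row i of omega
    without the diagonal entry).
    """
    if not 0 <= node < params.p:
        raise ConfigError(f"node index {node} out of range for p={params.p}")
    row = np.delete(params.omega[node], node)
    return float(params.tau[node]), row


def sample(
    params: IsingParameters,
    n: int,
    seed,
    method: str = "auto",
    burn_in: int = 1000,
    thinning: int = 10,
) -> np.ndarray:
    """Draw n joint states as an (n, p) int8 matrix.

    ``method`` is "exact" (inverse-CDF over the enumerated pmf, p <= 21),
    "gibbs" (sequential single-site updates with burn-in and thinning), or
    "auto" which picks exact whenever feasible. Deterministic under ``seed``.
    """
    if n < 1:
        raise DataError("sample size must be >= 1")
    rng = np.random.default_rng(seed)
    if method == "auto":
        method = "exact" if params.p <= MAX_EXACT_SAMPLING_P else "gibbs"
    if method == "exact":
        if params.p > MAX_EXACT_SAMPLING_P:
            raise EstimationError(
                f"exact sampling requires p <= {MAX_EXACT_SAMPLING_P}; use gibbs"
            )
        probs = enumerate_pmf(params)
        cdf = np.cumsum(probs)
        cdf[-1] = 1.0
        codes = np.searchsorted(cdf, rng.random(n), side="right")
        out = np.empty((n, params.p), dtype=np.int8)
        for i in range(params.p):
            out[:, i] = (codes >> i) & 1
        return out
    if method == "gibbs":
        if burn_in < 0 or thinning < 1:
            raise DataError(
                "gibbs sampling needs burn_in >= 0 and thinning >= 1 "
                "(zero iterations requested)"
            )
        total = burn_in + (n - 1) * thinning + 1
        init = (rng.random(params.p) < _logistic(params.tau)).astype(np.int8)
        uniforms = rng.random(total * params.p)
        return _kernels.gibbs_chain(
            params.tau.astype(float),
            params.omega.astype(float),
            n,
            burn_in,
            thinning,
            uniforms,
            init,
        )
    raise ConfigError(f"unknown sampling method {method!r}; expected exact|gibbs|auto")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


#: Default per-symptom endorsement targets spanning roughly 4-52%, ordered as
#: 11 alcohol then 10 cannabis items — the prevalence profile the generator
#: emulates.
DEFAULT_TARGET_RATES = (
    0.209, 0.454, 0.081, 0.342, 0.069, 0.430, 0.058, 0.266, 0.050, 0.054, 0.060,
    0.486, 0.374, 0.463, 0.203, 0.360, 0.166, 0.293, 0.393, 0.184, 0.124,
)


@dataclasses.dataclass
class GeneratorConfig:
    """Study-like cohort generator settings.

    Two disorder clusters with dense positive within-cluster couplings, a
    handful of weaker between-cluster "bridge" couplings, and thresholds
    calibrated so the marginal endorsement rates match ``target_endorsement_
    rates``. Within-cluster weights touching a node with a target rate below
    ``low_rate_threshold`` are multiplied by ``low_rate_weight_boost`` so
    rarely endorsed symptoms remain statistically detectable; the
    ``n_bridge_edges`` between-cluster weights are evenly spaced from the top
    of ``bridge_weight_range`` downward, giving one distinctly strongest
    bridge. ``forced_edges`` pins specific couplings (i, j, weight) before
    calibration. ``include_zero_variance_column`` overwrites the first
    cannabis column of the sampled cohort with all ones to exercise the
    degenerate-column exclusion rule downstream.
    """

    n: int = 1559
    cluster_sizes: tuple[int, int] = (11, 10)
    within_edge_probability: float = 1.0
    within_weight_range: tuple[float, float] = (0.35, 0.5)
    n_bridge_edges: int = 3
    bridge_weight_range: tuple[float, float] = (0.6, 1.5)
    low_rate_weight_boost: float = 1.6
    low_rate_threshold: float = 0.12
    target_endorsement_rates: Sequence[float] | None = None
    seed: int = 0
    include_zero_variance_column: bool = False
    forced_edges: tuple[tuple[int, int, float], ...] = ()
    calibration_tol: float = 0.005
    max_calibration_rounds: int = 200
    burn_in: int = 1000
    thinning: int = 10

    @property
    def p(self) -> int:
        return sum(self.cluster_sizes)

    def resolved_targets(self) -> np.ndarray:
        if self.target_endorsement_rates is None:
            if self.p == len(DEFAULT_TARGET_RATES):
                targets = np.asarray(DEFAULT_TARGET_RATES, dtype=float)
            else:
                # evenly spaced ladder over the same prevalence span
                targets = np.linspace(0.05, 0.5, self.p)
        else:
            targets = np.asarray(self.target_endorsement_rates, dtype=float)
        if targets.size != self.p:
            raise ConfigError(
                f"{targets.size} target rates supplied for p={self.p} nodes"
            )
        if np.any(targets <= 0.0) or np.any(targets >= 1.0):
            raise ConfigError("target endorsement rates must lie strictly in (0, 1)")
        return targets


@dataclasses.dataclass
class StudyLikeTruth:
    """Ground truth produced by :func:`make_study_like`."""

    params: IsingParameters
    edges: list[tuple[int, int, float]]
    bridge_edges: list[tuple[int, int, float]]
    symptom_labels: list[str]
    cluster_labels: list[str]
    config: GeneratorConfig
    calibration_rounds: int

    def edge_set(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.edges}

    def to_json(self) -> dict:
        p = self.params.p
        tril = [
            float(self.params.omega[i, j]) for i in range(p) for j in range(i)
        ]
        return {
            "tau": [float(t) for t in self.params.tau],
            "omega_lower_triangle": tril,
            "edges": [[int(i), int(j), float(w)] for i, j, w in self.edges],
            "bridge_edges": [
                [int(i), int(j), float(w)] for i, j, w in self.bridge_edges
            ],
            "symptom_labels": self.symptom_labels,
            "cluster_labels": self.cluster_labels,
            "seed": self.config.seed,
            "calibration_rounds": self.calibration_rounds,
        }

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_json(), handle, indent=2)


def calibrate_thresholds(
    omega: np.ndarray,
    targets: np.ndarray,
    tol: float = 0.005,
    max_rounds: int = 200,
) -> tuple[np.ndarray, int]:
    """Find tau so every exact marginal matches its target within ``tol``.

    Nodes are visited cyclically; each visit solves the monotone marginal
    equation for that node's threshold exactly (holding the others fixed),
    i.e. the limit of a bisection on tau_i. Raises when the loop over nodes
    does not converge, naming the worst node.
    """
    p = targets.size
    if p > MAX_ENUMERATION_P:
        raise EstimationError(
            f"threshold calibration enumerates 2^p states and needs p <= "
            f"{MAX_ENUMERATION_P}, got {p}"
        )
    # mean-field start: logit(target) minus the expected coupling input, so
    # the first enumeration pass is already near the right marginals
    tau0 = np.log(targets / (1.0 - targets)) - omega @ targets
    params = IsingParameters(tau0, omega)
    logw = _log_weights(params)
    logw -= logw.max()
    w = np.exp(logw)
    tau = tau0.copy()
    rounds, worst, worst_node = _kernels.calibration_rounds(
        w, tau, targets.astype(float), tol, max_rounds
    )
    if rounds == -2:
        raise ConvergenceError(
            f"threshold calibration diverged (weight mass under/overflow) at "
            f"node {worst_node}; couplings too extreme for these targets"
        )
    if rounds < 0:
        raise ConvergenceError(
            f"threshold calibration did not reach tolerance {tol} in "
            f"{max_rounds} rounds; worst node {worst_node} off by {worst:.4f}"
        )
    return tau, int(rounds)


def _cluster_labels(sizes: tuple[int, int]) -> tuple[list[str], list[str]]:
    n_a, n_c = sizes
    labels = [f"A{i + 1}" for i in range(n_a)] + [f"C{i + 1}" for i in range(n_c)]
    clusters = ["alcohol"] * n_a + ["cannabis"] * n_c
    return labels, clusters


def make_study_like(config: GeneratorConfig) -> StudyLikeTruth:
    """Draw a two-cluster coupling structure and calibrate its thresholds."""
    if len(config.cluster_sizes) != 2 or min(config.cluster_sizes) < 1:
        raise ConfigError("cluster_sizes must be two positive integers")
    p = config.p
    targets = config.resolved_targets()
    rng = np.random.default_rng(config.seed)
    n_a = config.cluster_sizes[0]

    def boost(i: int, j: int) -> float:
        if min(targets[i], targets[j]) < config.low_rate_threshold:
            return config.low_rate_weight_boost
        return 1.0

    omega = np.zeros((p, p))
    blocks = (range(0, n_a), range(n_a, p))
    for block in blocks:
        nodes = list(block)
        # ring backbone (first and second neighbours) keeps every node at
        # degree >= 4 so each disorder cluster stays one cohesive block even
        # after imperfect edge recovery
        m = len(nodes)
        backbone = set()
        if m >= 2:
            for step in (1, 2):
                if m > 2 * step or (step == 1 and m == 2):
                    for k in range(m if m > 2 * step else m - 1):
                        pair = (nodes[k], nodes[(k + step) % m])
                        backbone.add((min(pair), max(pair)))
        for i, j in sorted(backbone):
            w = rng.uniform(*config.within_weight_range) * boost(i, j)
            omega[i, j] = omega[j, i] = w
        for ai, i in enumerate(nodes):
            for j in nodes[ai + 1 :]:
                if omega[i, j] == 0.0 and rng.random() < config.within_edge_probability:
                    w = rng.uniform(*config.within_weight_range) * boost(i, j)
                    omega[i, j] = omega[j, i] = w

    cross_pairs = [(i, j) for i in blocks[0] for j in blocks[1]]
    if config.n_bridge_edges > len(cross_pairs):
        raise ConfigError(
            f"{config.n_bridge_edges} bridge edges requested but only "
            f"{len(cross_pairs)} between-cluster pairs exist"
        )
    bridge_edges: list[tuple[int, int, float]] = []
    if config.n_bridge_edges > 0:
        chosen = rng.choice(len(cross_pairs), size=config.n_bridge_edges, replace=False)
        lo, hi = config.bridge_weight_range
        spaced = np.linspace(hi, lo, config.n_bridge_edges)
        for w, idx in zip(spaced, np.sort(chosen)):
            i, j = cross_pairs[int(idx)]
            omega[i, j] = omega[j, i] = float(w)
            bridge_edges.append((i, j, float(w)))

    for i, j, w in config.forced_edges:
        if not (0 <= i < p and 0 <= j < p) or i == j:
            raise ConfigError(f"forced edge ({i}, {j}) is not a valid node pair")
        omega[i, j] = omega[j, i] = float(w)
        bridge_edges = [e for e in bridge_edges if {e[0], e[1]} != {i, j}]
        if (i < n_a) != (j < n_a):
            bridge_edges.append((min(i, j), max(i, j), float(w)))

    tau, rounds = calibrate_thresholds(
        omega, targets, config.calibration_tol, config.max_calibration_rounds
    )
    params = IsingParameters(tau, omega)
    edges = [
        (i, j, float(omega[i, j]))
        for i in range(p)
        for j in range(i + 1, p)
        if omega[i, j] != 0.0
    ]
    labels, clusters = _cluster_labels(config.cluster_sizes)
    return StudyLikeTruth(params, edges, bridge_edges, labels, clusters, config, rounds)


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, StudyLikeTruth]:
    """Sample a study-like cohort as a respondent-by-symptom 0/1 table.

    Structure and sampling randomness both derive from ``config.seed``.
    Models within the enumeration limit are sampled exactly (iid inverse-CDF
    draws); larger models fall back to Gibbs.
    """
    truth = make_study_like(config)
    sample_seed = np.random.SeedSequence([config.seed, 1])
    matrix = sample(
        truth.params,
        config.n,
        sample_seed,
        method="auto",
        burn_in=config.burn_in,
        thinning=config.thinning,
    )
    frame = pd.DataFrame(matrix, columns=truth.symptom_labels)
    if config.include_zero_variance_column:
        first_cannabis = truth.cluster_labels.index("cannabis")
        frame[truth.symptom_labels[first_cannabis]] = 1
    return frame, truth
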