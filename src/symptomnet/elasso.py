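"""Ising network estimation by nodewise L1 logistic regression with EBIC.

Each binary node is regressed on all the others with an L1 penalty along a
decreasing lambda path (cyclic coordinate descent on the IRLS quadratic
approximation, warm starts). The per-node model is the path point minimizing
the extended Bayesian information criterion; the nodewise coefficient
matrices are then symmetrized with the AND (default) or OR rule into a
weighted undirected network, and the selected intercepts become the node
thresholds.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np

from . import _kernels
from .data_prep import SymptomData
from .errors import ConfigError, ConvergenceError, DataError, EstimationError
from .graph import NetworkGraph
from .ising import IsingParameters

__all__ = [
    "EstimationConfig",
    "LassoPath",
    "NodewiseFit",
    "lambda_max",
    "logistic_lasso_path",
    "ebic",
    "fit_node",
    "symmetrize",
    "estimate_network",
]

#: A nodewise coefficient beyond this magnitude (log-odds) marks a diverging,
#: likely separated fit.
_STABILITY_BOUND = 30.0


@dataclasses.dataclass
class EstimationConfig:
    """Settings for the nodewise estimator.

    gamma is the EBIC hyperparameter (0 recovers classical BIC); the lambda
    path has ``n_lambda`` log-spaced points from lambda_max down to
    ``lambda_min_ratio * lambda_max``. ``rule`` is "AND" (edge kept only when
    both regressions select it) or "OR".
    """

    gamma: float = 0.25
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    rule: str = "AND"
    tol: float = 1e-6
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ConfigError("gamma must be >= 0")
        if not 0 < self.lambda_min_ratio < 1:
            raise ConfigError("lambda_min_ratio must lie in (0, 1)")
        if self.rule not in ("AND", "OR"):
            raise ConfigError(f"rule must be AND or OR, got {self.rule!r}")
        if self.n_lambda < 1:
            raise ConfigError("n_lambda must be >= 1")


@dataclasses.dataclass
class LassoPath:
    """Solution path of one penalized logistic regression."""

    lambdas: np.ndarray
    intercepts: np.ndarray
    coefs: np.ndarray  # (n_lambda, n_predictors)
    loglik: np.ndarray
    n_iter: np.ndarray
    converged: np.ndarray


def lambda_max(y: np.ndarray, X: np.ndarray, sample_weight: np.ndarray | None = None) -> float:
    """Smallest penalty at which every coefficient is exactly zero (KKT)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    sw = np.ones(y.size) if sample_weight is None else np.asarray(sample_weight, float)
    n_eff = sw.sum()
    ybar = float(sw @ y) / n_eff
    grad = (sw * (y - ybar)) @ X / n_eff
    return float(np.max(np.abs(grad)))


def logistic_lasso_path(
    y: np.ndarray,
    X: np.ndarray,
    lambdas: np.ndarray,
    sample_weight: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    raise_on_fail: bool = True,
) -> LassoPath:
    """Fit the penalized path, ordered from the largest lambda downward.

    Minimizes mean negative log-likelihood + lambda * sum |beta| with an
    unpenalized intercept. Raises :class:`ConvergenceError` naming the
    offending lambda unless ``raise_on_fail`` is disabled (then inspect
    ``converged``).
    """
    y = np.ascontiguousarray(y, dtype=np.float64)
    X = np.ascontiguousarray(X, dtype=np.float64)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise DataError("y and X must have matching first dimensions")
    if np.any((y != 0) & (y != 1)):
        raise DataError("response must be binary 0/1")
    col_sd = X.std(axis=0)
    if np.any(col_sd == 0.0):
        raise DataError("X contains an all-constant column")
    if y.std() == 0.0:
        raise DataError("response has no variance")
    sw = (
        np.ones(y.size, dtype=np.float64)
        if sample_weight is None
        else np.ascontiguousarray(sample_weight, dtype=np.float64)
    )
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    if lambdas.size > 1 and np.any(np.diff(lambdas) > 0):
        raise ConfigError("lambda path must be non-increasing")
    binary = bool(np.all((X == 0.0) | (X == 1.0)))
    if binary:
        n, p = X.shape
        # CSR over the 1-entries, by row and by column
        rows, cols = np.nonzero(X)
        row_idx = cols.astype(np.int64)
        row_ptr = np.zeros(n + 1, dtype=np.int64)
        row_ptr[1:] = np.cumsum(np.bincount(rows, minlength=n))
        order = np.argsort(cols, kind="stable")
        col_idx = rows[order].astype(np.int64)
        col_ptr = np.zeros(p + 1, dtype=np.int64)
        col_ptr[1:] = np.cumsum(np.bincount(cols, minlength=p))
        intercepts, coefs, n_iter, converged = _kernels.lasso_path_binary(
            col_idx, col_ptr, row_idx, row_ptr, y, sw,
            n, p, lambdas, tol, max_iter, 10 * max_iter,
        )
    else:
        intercepts, coefs, n_iter, converged = _kernels.lasso_path_dense(
            X, y, sw, lambdas, tol, max_iter, 10 * max_iter
        )
    # numerically-zero survivors of the soft threshold are not selections
    coefs[np.abs(coefs) < 1e-10] = 0.0
    # weighted log-likelihood of every path point, vectorized over the grid
    etas = intercepts[:, None] + coefs @ X.T
    loglik = (y[None, :] * etas - np.logaddexp(0.0, etas)) @ sw
    if raise_on_fail and not converged.all():
        idx = int(np.argmin(converged))
        raise ConvergenceError(
            f"coordinate descent did not converge at lambda={lambdas[idx]:.6g} "
            f"after {int(n_iter[idx])} outer iterations"
        )
    return LassoPath(lambdas, intercepts, coefs, loglik, n_iter, converged)


def ebic(loglik: float, k_nonzero: int, n: int, n_candidate_predictors: int, gamma: float) -> float:
    """Extended BIC: -2 loglik + k log n + 2 gamma k log(#candidates)."""
    if n < 1 or n_candidate_predictors < 1:
        raise ConfigError("n and n_candidate_predictors must be >= 1")
    return (
        -2.0 * loglik
        + k_nonzero * np.log(n)
        + 2.0 * gamma * k_nonzero * np.log(n_candidate_predictors)
    )


@dataclasses.dataclass
class NodewiseFit:
    """EBIC-selected regression of one node on all the others."""

    node: int
    label: str
    intercept: float
    coefficients: np.ndarray  # length p, entry for the node itself fixed at 0
    selected_lambda: float
    selected_index: int
    ebic_value: float
    lambdas: np.ndarray
    ebic_path: np.ndarray
    separation_flag: bool


def _lambda_grid(lam_max: float, config: EstimationConfig) -> np.ndarray:
    if lam_max <= 0:
        # response uncorrelated with every predictor: any positive penalty
        # keeps the null model; use a token grid
        return np.array([1e-3])
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)


def fit_node(
    data: SymptomData,
    node: int,
    config: EstimationConfig | None = None,
    sample_weight: np.ndarray | None = None,
    lambdas: np.ndarray | None = None,
) -> NodewiseFit:
    """Penalized path for one node, model chosen by EBIC (ties -> larger lambda).

    Diverging fits (perfect or quasi-separation) are excluded from selection;
    if any path point diverged a warning names the node and the coefficients
    of the best stable lambda are returned.
    """
    config = config or EstimationConfig()
    p = data.p
    if not 0 <= node < p:
        raise ConfigError(f"node index {node} out of range for p={p}")
    y = data.matrix[:, node].astype(np.float64)
    others = [j for j in range(p) if j != node]
    X = data.matrix[:, others].astype(np.float64)
    if lambdas is None:
        lambdas = _lambda_grid(lambda_max(y, X, sample_weight), config)
    path = logistic_lasso_path(
        y,
        X,
        lambdas,
        sample_weight=sample_weight,
        tol=config.tol,
        max_iter=config.max_iter,
        raise_on_fail=False,
    )
    n_eff = data.n if sample_weight is None else float(np.sum(sample_weight))
    k = (path.coefs != 0.0).sum(axis=1)
    ebic_path = np.array(
        [
            ebic(path.loglik[l], int(k[l]), int(round(n_eff)), p - 1, config.gamma)
            for l in range(lambdas.size)
        ]
    )
    stable = (
        path.converged
        & (np.abs(path.intercepts) <= _STABILITY_BOUND)
        & (np.abs(path.coefs).max(axis=1) <= _STABILITY_BOUND)
    )
    if not stable.any():
        raise EstimationError(
            f"no stable penalized fit for node {data.symptom_labels[node]!r}"
        )
    separation = bool(~stable.all())
    if separation:
        warnings.warn(
            f"node {data.symptom_labels[node]!r}: diverging fit on part of the "
            "lambda path (possible separation); selection restricted to stable "
            "lambdas",
            RuntimeWarning,
            stacklevel=2,
        )
    masked = np.where(stable, ebic_path, np.inf)
    sel = int(np.argmin(masked))  # first occurrence = largest lambda on ties
    coefficients = np.zeros(p)
    coefficients[others] = path.coefs[sel]
    return NodewiseFit(
        node=node,
        label=data.symptom_labels[node],
        intercept=float(path.intercepts[sel]),
        coefficients=coefficients,
        selected_lambda=float(lambdas[sel]),
        selected_index=sel,
        ebic_value=float(ebic_path[sel]),
        lambdas=lambdas,
        ebic_path=ebic_path,
        separation_flag=separation,
    )


def symmetrize(coef_matrix: np.ndarray, rule: str = "AND") -> np.ndarray:
    """Combine nodewise coefficients B (B[i, j] = effect of j on i) into a
    symmetric adjacency: mean of the two coefficients, kept only when both
    (AND) or at least one (OR) is nonzero. Exact zeros elsewhere."""
    B = np.asarray(coef_matrix, dtype=float)
    both = (B != 0.0) & (B.T != 0.0)
    either = (B != 0.0) | (B.T != 0.0)
    keep = both if rule == "AND" else either
    W = np.where(keep, (B + B.T) / 2.0, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def estimate_network(
    data: SymptomData,
    config: EstimationConfig | None = None,
    sample_weight: np.ndarray | None = None,
    lambdas: np.ndarray | None = None,
    return_fits: bool = False,
):
    """Run fit_node for every node and symmetrize into a NetworkGraph.

    Returns (NetworkGraph, IsingParameters); with ``return_fits`` the list of
    :class:`NodewiseFit` is appended. Thresholds are the selected intercepts.
    """
    config = config or EstimationConfig()
    rates = data.endorsement_rates()
    degenerate = np.flatnonzero((rates == 0.0) | (rates == 1.0))
    if degenerate.size:
        raise DataError(
            "data contain zero-variance columns "
            f"{[data.symptom_labels[j] for j in degenerate]}; run prepare_matrix first"
        )
    p = data.p
    B = np.zeros((p, p))
    tau = np.zeros(p)
    fits = []
    for node in range(p):
        fit = fit_node(data, node, config, sample_weight=sample_weight, lambdas=lambdas)
        B[node] = fit.coefficients
        tau[node] = fit.intercept
        fits.append(fit)
    W = symmetrize(B, config.rule)
    graph = NetworkGraph(W, list(data.symptom_labels))
    params = IsingParameters(tau, W)
    if return_fits:
        return graph, params, fits
    return graph, params


def write_thresholds_json(params: IsingParameters, labels, path) -> None:
    payload = {str(l): float(t) for l, t in zip(labels, params.tau)}
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2)
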