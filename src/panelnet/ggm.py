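"""Regularized partial-correlation networks (graphical lasso + EBIC).

A cross-sectional symptom network is a Gaussian graphical model: nodes are
items, edges are partial correlations conditioned on all remaining items.
Estimation follows the standard psychometric-network recipe: compute the
sample correlation matrix, solve the L1-penalized Gaussian likelihood over a
descending penalty path, and pick the path point minimizing the extended
Bayesian information criterion

    EBIC(lambda) = -2 loglik + E log n + 4 gamma E log p,

where E is the number of nonzero edges.  Larger gamma prefers sparser
networks; ties break toward the sparser model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._glasso import glasso, glasso_warm
from .panel_io import PanelDataset, wave_matrix

__all__ = [
    "GGMConfig",
    "WeightedNetwork",
    "PathPoint",
    "sample_correlation",
    "glasso_path",
    "ebic_select",
    "fit_ggm",
    "edge_list",
    "precision_to_partial",
    "network_to_graphml",
    "network_to_adjacency_csv",
    "edge_list_to_tsv",
]

EDGE_EPS = 1e-8  # below this magnitude an optimized weight is floating-point noise


@dataclass(frozen=True)
class GGMConfig:
    """Tuning knobs of the network estimator.

    gamma: EBIC sparsity hyperparameter (0 reduces to BIC; 0.5 is the
    conventional default).  The penalty path has ``n_lambda`` log-spaced
    points from the saturation penalty (empty network) down to
    ``lambda_min_ratio`` times it.
    """

    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    correlation_kind: str = "pearson"

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not (0 < self.lambda_min_ratio < 1):
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.correlation_kind not in ("pearson", "spearman"):
            raise ValueError("correlation_kind must be 'pearson' or 'spearman'")


@dataclass
class WeightedNetwork:
    """Symmetric partial-correlation network for one wave."""

    nodes: tuple[str, ...]
    weights: np.ndarray
    lambda_selected: float = np.nan

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        p = len(self.nodes)
        if self.weights.shape != (p, p):
            raise ValueError("weights must be p x p")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        self.weights = 0.5 * (self.weights + self.weights.T)
        np.fill_diagonal(self.weights, 0.0)
        if np.any(np.abs(self.weights) >= 1.0):
            raise ValueError("edge weights must lie in (-1, 1)")

    @property
    def p(self) -> int:
        return len(self.nodes)

    @property
    def nonzero_edges(self) -> int:
        iu = np.triu_indices(self.p, 1)
        return int(np.sum(np.abs(self.weights[iu]) > 0))

    def upper_triangle(self) -> np.ndarray:
        return self.weights[np.triu_indices(self.p, 1)]


@dataclass(frozen=True)
class PathPoint:
    lam: float
    precision: np.ndarray
    loglik: float
    n_edges: int


class ConvergenceError(RuntimeError):
    pass


def sample_correlation(
    data: PanelDataset | np.ndarray,
    wave: str | int | None = None,
    kind: str = "pearson",
) -> np.ndarray:
    """Item-by-item correlation matrix of one wave (complete data only).

    Accepts either a PanelDataset plus a wave label or a plain (n, p) score
    matrix.  A zero-variance item raises, naming the item, because its
    correlations are undefined.
    """
    if isinstance(data, PanelDataset):
        X = wave_matrix(data, wave if wave is not None else 0)
        names = data.schema.item_ids
    else:
        X = np.asarray(data, dtype=float)
        names = tuple(str(i) for i in range(X.shape[1]))
    sd = X.std(axis=0)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"item {names[j]!r} has zero variance")
    if kind == "spearman":
        X = np.apply_along_axis(stats.rankdata, 0, X)
    elif kind != "pearson":
        raise ValueError("kind must be 'pearson' or 'spearman'")
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def _gaussian_loglik(R: np.ndarray, precision: np.ndarray, n: int) -> float:
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - np.trace(R @ precision))


def glasso_path(
    R: np.ndarray, n: int, config: GGMConfig = GGMConfig()
) -> list[PathPoint]:
    """Graphical-lasso solutions over a descending penalty path.

    The path starts at the saturation penalty max|off-diag R| (empty network)
    and decreases geometrically; each point is warm-started from the previous
    one.  Returned in computation order, i.e. lambda descending.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    lam_max = float(np.max(np.abs(R - np.diag(np.diag(R)))))
    if lam_max <= 0:
        lam_max = 1e-3
    lams = np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)
    iu = np.triu_indices(p, 1)
    W = R.copy()
    Bwork = np.zeros_like(R)
    out: list[PathPoint] = []
    for lam in lams:
        theta, converged, sweeps = glasso_warm(R, lam, W, Bwork)
        if not converged:
            raise ConvergenceError(
                f"graphical lasso did not converge at lambda={lam:.4g} ({sweeps} sweeps)"
            )
        n_edges = int(np.sum(np.abs(theta[iu]) > EDGE_EPS))
        out.append(PathPoint(float(lam), theta.copy(), _gaussian_loglik(R, theta, n), n_edges))
    return out


def precision_to_partial(precision: np.ndarray) -> np.ndarray:
    """Partial correlations w_ij = -theta_ij / sqrt(theta_ii theta_jj)."""
    d = np.sqrt(np.diag(precision))
    W = -precision / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    W[np.abs(W) < EDGE_EPS] = 0.0
    return np.clip(W, -0.999999, 0.999999)


def ebic_select(
    path: list[PathPoint],
    n: int,
    gamma: float = 0.5,
    p: int | None = None,
    nodes: tuple[str, ...] | None = None,
) -> WeightedNetwork:
    """Pick the path point minimizing the EBIC; ties go to larger lambda.

    The winning precision matrix is converted to the partial-correlation
    scale for the returned network.
    """
    if not path:
        raise ValueError("empty path")
    if p is None:
        p = path[0].precision.shape[0]
    scores = np.array(
        [-2.0 * pt.loglik + pt.n_edges * np.log(n) + 4.0 * gamma * pt.n_edges * np.log(p)
         for pt in path]
    )
    lams = np.array([pt.lam for pt in path])
    best = np.flatnonzero(scores == scores.min())
    winner = best[np.argmax(lams[best])]
    pt = path[winner]
    W = precision_to_partial(pt.precision)
    if nodes is None:
        nodes = tuple(str(i) for i in range(p))
    return WeightedNetwork(nodes=nodes, weights=W, lambda_selected=pt.lam)


def fit_ggm(
    data: PanelDataset | np.ndarray,
    wave: str | int | None = None,
    config: GGMConfig = GGMConfig(),
) -> WeightedNetwork:
    """Full per-wave pipeline: correlation -> glasso path -> EBIC selection."""
    if isinstance(data, PanelDataset):
        X = wave_matrix(data, wave if wave is not None else 0)
        nodes = data.schema.item_ids
    else:
        X = np.asarray(data, dtype=float)
        nodes = tuple(str(i) for i in range(X.shape[1]))
    R = sample_correlation(X, kind=config.correlation_kind)
    n = X.shape[0]
    path = glasso_path(R, n, config)
    return ebic_select(path, n, gamma=config.gamma, p=len(nodes), nodes=nodes)


def edge_list(
    net: WeightedNetwork, nonzero_only: bool = False
) -> list[tuple[str, str, float]]:
    """Upper-triangle edges in stable lexicographic (node-order) enumeration."""
    out = []
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w = float(net.weights[i, j])
            if nonzero_only and abs(w) <= 0:
                continue
            out.append((net.nodes[i], net.nodes[j], w))
    return out


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def network_to_adjacency_csv(net: WeightedNetwork, path) -> None:
    pd.DataFrame(net.weights, index=net.nodes, columns=net.nodes).to_csv(path)


def edge_list_to_tsv(net: WeightedNetwork, path, nonzero_only: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\tweight\n")
        for a, b, w in edge_list(net, nonzero_only=nonzero_only):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def network_to_graphml(net: WeightedNetwork, path) -> None:
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(net.nodes)
    for a, b, w in edge_list(net, nonzero_only=True):
        G.add_edge(a, b, weight=w)
    nx.write_graphml(G, path)
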