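"""Cross-lagged panel network: node-wise lasso regressions across waves.

Each wave-2 symptom is regressed on all 22 wave-1 symptoms with an L1
penalty whose strength is chosen by k-fold cross-validation (default
10-fold, CV-minimum rule).  The resulting p x p coefficient matrix B has
autoregressive paths on the diagonal (a symptom predicting itself a year
later) and cross-lagged paths off the diagonal.  Variables are standardized
per wave before fitting so coefficients are comparable across items and the
in/out expected-influence sums are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .panel_io import PanelDataset, wave_matrix

__all__ = [
    "DirectedNetwork",
    "fit_clpn",
    "zero_autoregressive",
    "threshold_edges",
    "directed_to_adjacency_csv",
    "directed_edge_list_to_tsv",
    "directed_to_graphml",
]


@dataclass
class DirectedNetwork:
    """p x p cross-lagged coefficient matrix.

    Entry [i, j] is the effect of wave-1 item i on wave-2 item j; the
    diagonal holds the autoregressive paths.  Columns are fit independently,
    so modifying one outcome's regression leaves the others untouched.
    """

    nodes: tuple[str, ...]
    B_hat: np.ndarray
    lambda_per_outcome: np.ndarray | None = None
    standardized: bool = True

    def __post_init__(self):
        self.B_hat = np.asarray(self.B_hat, dtype=float)
        p = len(self.nodes)
        if self.B_hat.shape != (p, p):
            raise ValueError("B_hat must be p x p")

    @property
    def p(self) -> int:
        return len(self.nodes)

    def copy(self) -> "DirectedNetwork":
        return DirectedNetwork(
            nodes=self.nodes,
            B_hat=self.B_hat.copy(),
            lambda_per_outcome=None
            if self.lambda_per_outcome is None
            else self.lambda_per_outcome.copy(),
            standardized=self.standardized,
        )


def _standardize(X: np.ndarray, names) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"item {names[j]!r} has zero variance")
    return (X - X.mean(axis=0)) / sd


def fit_clpn(
    data: PanelDataset | tuple[np.ndarray, np.ndarray],
    folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    one_se_rule: bool = False,
    n_alphas: int = 100,
    penalty: float | None = None,
) -> DirectedNetwork:
    """Fit the directed network by one cross-validated lasso per outcome.

    ``data`` is a complete PanelDataset, or a ``(X1, X2)`` pair of (n, p)
    arrays (e.g. the generator's latent scores, for recovery studies).  Fold
    assignment is a simple seeded random partition, shared across outcomes,
    so results are deterministic given ``seed``.  ``one_se_rule`` switches
    penalty selection from the CV-minimum to the more conservative
    largest-penalty-within-one-SE rule.
    """
    if isinstance(data, PanelDataset):
        X1 = wave_matrix(data, 0)
        X2 = wave_matrix(data, 1)
        nodes = data.schema.item_ids
    else:
        X1, X2 = (np.asarray(a, dtype=float) for a in data)
        nodes = tuple(str(i) for i in range(X1.shape[1]))
    n, p = X1.shape
    if X2.shape != (n, p):
        raise ValueError("wave matrices must agree in shape")
    if folds < 2 or folds > n:
        raise ValueError("folds must be in [2, n]")
    if standardize:
        X1 = _standardize(X1, nodes)
        X2 = _standardize(X2, nodes)
    else:
        _standardize(X1, nodes)  # still reject degenerate items
        _standardize(X2, nodes)

    cv = KFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**32 - 1))
    B = np.zeros((p, p))
    lams = np.zeros(p)
    if penalty is not None:
        # fixed penalty, no cross-validation; 0 is the OLS solution
        Xc = np.column_stack([np.ones(n), X1])
        for j in range(p):
            y = X2[:, j]
            if penalty == 0.0:
                coef, *_ = np.linalg.lstsq(Xc, y, rcond=None)
                B[:, j] = coef[1:]
            else:
                fit = Lasso(alpha=penalty, fit_intercept=True, max_iter=50_000)
                fit.fit(X1, y)
                B[:, j] = fit.coef_
            lams[j] = penalty
        return DirectedNetwork(nodes=nodes, B_hat=B, lambda_per_outcome=lams,
                               standardized=standardize)
    for j in range(p):
        y = X2[:, j]
        model = LassoCV(cv=cv, alphas=n_alphas, fit_intercept=True, max_iter=50_000)
        model.fit(X1, y)
        alpha = model.alpha_
        if one_se_rule:
            mse = model.mse_path_.mean(axis=1)
            se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(folds)
            k = int(np.argmin(mse))
            ok = np.flatnonzero(mse <= mse[k] + se[k])
            # alphas_ is descending; the smallest index is the largest penalty
            alpha = model.alphas_[ok.min()]
            refit = Lasso(alpha=alpha, fit_intercept=True, max_iter=50_000)
            refit.fit(X1, y)
            B[:, j] = refit.coef_
        else:
            B[:, j] = model.coef_
        lams[j] = alpha
    return DirectedNetwork(nodes=nodes, B_hat=B, lambda_per_outcome=lams,
                           standardized=standardize)


def zero_autoregressive(net: DirectedNetwork) -> DirectedNetwork:
    """Copy with the diagonal (autoregressive paths) set exactly to 0.

    The study's display convention: autoregressive paths dominate the plot
    and are removed to highlight cross-lagged effects.  Idempotent.
    """
    out = net.copy()
    np.fill_diagonal(out.B_hat, 0.0)
    return out


def threshold_edges(net: DirectedNetwork, beta_min: float = 0.05) -> DirectedNetwork:
    """Copy with |coefficients| < beta_min zeroed (display transform only).

    The boundary is kept: an entry exactly equal to beta_min survives.
    """
    if beta_min < 0:
        raise ValueError("beta_min must be >= 0")
    out = net.copy()
    out.B_hat[np.abs(out.B_hat) < beta_min] = 0.0
    return out


def directed_to_adjacency_csv(net: DirectedNetwork, path) -> None:
    pd.DataFrame(net.B_hat, index=net.nodes, columns=net.nodes).to_csv(path)


def directed_edge_list_to_tsv(net: DirectedNetwork, path, nonzero_only: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write("from\tto\tbeta\n")
        for i in range(net.p):
            for j in range(net.p):
                b = float(net.B_hat[i, j])
                if nonzero_only and b == 0.0:
                    continue
                fh.write(f"{net.nodes[i]}\t{net.nodes[j]}\t{b:.10g}\n")


def directed_to_graphml(net: DirectedNetwork, path) -> None:
    import networkx as nx

    G = nx.DiGraph()
    G.add_nodes_from(net.nodes)
    for i in range(net.p):
        for j in range(net.p):
            if net.B_hat[i, j] != 0.0:
                G.add_edge(net.nodes[i], net.nodes[j], weight=float(net.B_hat[i, j]))
    nx.write_graphml(G, path)
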