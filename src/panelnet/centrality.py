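"""Expected-influence centralities.

Expected influence (EI) of a node in an undirected network is the signed
sum of its edge weights -- unlike strength it does not take absolute values,
so inhibitory edges reduce a node's influence.  For the directed cross-lag
matrix the analogues are out expected influence (OEI, sum of outgoing
cross-lagged coefficients) and in expected influence (IEI, sum of incoming
ones); autoregressive paths are excluded by default because these are
defined as cross-lagged centralities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clpn import DirectedNetwork
from .ggm import WeightedNetwork

__all__ = [
    "CentralityTable",
    "expected_influence",
    "in_out_expected_influence",
    "rank_centrality",
    "centrality_to_csv",
]


@dataclass
class CentralityTable:
    """Per-node centrality values with z-standardized companions.

    z uses the population SD across the p nodes (the plotting convention for
    centrality panels); when all raw values are equal, z is all zeros.
    """

    nodes: tuple[str, ...]
    metric: str
    raw: np.ndarray

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (len(self.nodes),):
            raise ValueError("raw must have one value per node")

    @property
    def z(self) -> np.ndarray:
        sd = self.raw.std(ddof=0)
        if sd == 0:
            return np.zeros_like(self.raw)
        return (self.raw - self.raw.mean()) / sd

    def as_series(self) -> pd.Series:
        return pd.Series(self.raw, index=list(self.nodes), name=self.metric)


def expected_influence(net: WeightedNetwork) -> CentralityTable:
    """One-step expected influence: EI(i) = sum_j w_ij (signed)."""
    return CentralityTable(nodes=net.nodes, metric="EI", raw=net.weights.sum(axis=1))


def in_out_expected_influence(
    net: DirectedNetwork, include_autoregressive: bool = False
) -> tuple[CentralityTable, CentralityTable]:
    """(IEI, OEI): column and row sums of the cross-lag matrix.

    With the default flag, the diagonal (autoregressive paths) is excluded
    from both sums.
    """
    B = net.B_hat.copy()
    if not include_autoregressive:
        np.fill_diagonal(B, 0.0)
    iei = CentralityTable(nodes=net.nodes, metric="IEI", raw=B.sum(axis=0))
    oei = CentralityTable(nodes=net.nodes, metric="OEI", raw=B.sum(axis=1))
    return iei, oei


def rank_centrality(table: CentralityTable) -> list[str]:
    """Nodes in descending raw-value order; ties keep node order (stable)."""
    if len(table.nodes) == 0:
        raise ValueError("empty centrality table")
    order = np.argsort(-table.raw, kind="stable")
    return [table.nodes[i] for i in order]


def centrality_to_csv(tables: list[CentralityTable], path) -> None:
    rows = []
    for t in tables:
        z = t.z
        for i, node in enumerate(t.nodes):
            rows.append({"node": node, "metric": t.metric, "raw": t.raw[i], "z": z[i]})
    pd.DataFrame(rows).to_csv(path, index=False)
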