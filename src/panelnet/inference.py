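"""Resampling machinery: permutation network comparison, nonparametric
bootstrap edge CIs, edge/centrality difference tests, and the case-drop
bootstrap with the correlation stability (CS) coefficient.

All resampling is reproducible: replicate k draws from a generator seeded by
(seed, k), so results do not depend on execution order or chunking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .centrality import expected_influence, in_out_expected_influence
from .clpn import fit_clpn, zero_autoregressive
from .ggm import ConvergenceError, GGMConfig, WeightedNetwork, fit_ggm
from .panel_io import PanelDataset, wave_matrix

__all__ = [
    "NCTResult",
    "ResamplingResult",
    "global_strength",
    "nct_global",
    "bootstrap_edges",
    "difference_test",
    "case_drop_cs",
    "DEFAULT_DROP_GRID",
]

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))


def global_strength(net: WeightedNetwork) -> float:
    """Overall connectivity: sum of absolute edge weights over unique pairs."""
    return float(np.abs(net.upper_triangle()).sum())


@dataclass
class NCTResult:
    """Permutation test of equal overall connectivity between two networks.

    p_value uses the add-one convention
    p = (1 + #{S_perm >= S_obs}) / (1 + n_permutations), so it is never 0.
    """

    S_observed: float
    p_value: float
    n_permutations: int
    per_permutation_S: np.ndarray
    strength_a: float
    strength_b: float


@dataclass
class ResamplingResult:
    """Replicate store plus derived summaries for one resampling run."""

    nodes: tuple[str, ...]
    point_edges: np.ndarray | None = None  # (E,) upper-triangle point estimates
    point_centrality: np.ndarray | None = None  # (p,)
    replicate_edges: np.ndarray | None = None  # (B, E)
    replicate_centrality: np.ndarray | None = None  # (B, p)
    edge_ci: np.ndarray | None = None  # (E, 2)
    ci_level: float = 0.95
    n_failed: int = 0
    cs_curves: dict[float, np.ndarray] = field(default_factory=dict)
    cs_coefficient: float | None = None
    metric: str | None = None


def _as_matrix(data, wave):
    if isinstance(data, PanelDataset):
        return wave_matrix(data, wave if wave is not None else 0), data.schema.item_ids
    X = np.asarray(data, dtype=float)
    return X, tuple(str(i) for i in range(X.shape[1]))


def nct_global(
    data_a,
    data_b,
    n_permutations: int = 1000,
    config: GGMConfig = GGMConfig(),
    seed: int = 0,
    wave_a=None,
    wave_b=None,
    paired: bool = False,
) -> NCTResult:
    """Network comparison test for overall connectivity.

    Both networks are re-estimated with the full glasso+EBIC procedure, for
    the observed split and for every permutation.  The default scheme pools
    participants and randomly re-partitions them into the original group
    sizes (the two waves treated as independent groups, as in the study's
    baseline-vs-follow-up comparison).  ``paired=True`` instead permutes the
    wave labels within participant, respecting the repeated-measures design;
    it requires equal group sizes with aligned rows.
    """
    if n_permutations < 20:
        raise ValueError("n_permutations must be >= 20 for usable p-value resolution")
    Xa, nodes = _as_matrix(data_a, wave_a)
    Xb, nodes_b = _as_matrix(data_b, wave_b)
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError("groups must share the item schema")
    na, nb = Xa.shape[0], Xb.shape[0]
    if paired and na != nb:
        raise ValueError("paired permutation requires equal group sizes")

    def strength_of(X):
        return global_strength(fit_ggm(X, config=config))

    gs_a, gs_b = strength_of(Xa), strength_of(Xb)
    S_obs = abs(gs_a - gs_b)

    pooled = np.vstack([Xa, Xb])
    S_perm = np.empty(n_permutations)
    for k in range(n_permutations):
        rng = np.random.default_rng([seed, k])
        if paired:
            swap = rng.random(na) < 0.5
            Pa = np.where(swap[:, None], Xb, Xa)
            Pb = np.where(swap[:, None], Xa, Xb)
        else:
            idx = rng.permutation(na + nb)
            Pa, Pb = pooled[idx[:na]], pooled[idx[na:]]
        S_perm[k] = abs(strength_of(Pa) - strength_of(Pb))

    p_value = (1.0 + np.sum(S_perm >= S_obs)) / (1.0 + n_permutations)
    return NCTResult(
        S_observed=S_obs,
        p_value=float(p_value),
        n_permutations=n_permutations,
        per_permutation_S=S_perm,
        strength_a=gs_a,
        strength_b=gs_b,
    )


def bootstrap_edges(
    data,
    n_boot: int = 1000,
    config: GGMConfig = GGMConfig(),
    seed: int = 0,
    wave=None,
    ci_level: float = 0.95,
    max_failure_rate: float = 0.05,
) -> ResamplingResult:
    """Nonparametric bootstrap of the GGM: percentile CIs per edge weight.

    Participants are resampled with replacement; the network (and its
    expected-influence centralities) is re-estimated per replicate.  A
    replicate whose estimation fails is dropped and counted; more than
    ``max_failure_rate`` failures aborts.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    X, nodes = _as_matrix(data, wave)
    n, p = X.shape
    net = fit_ggm(X, config=config)
    point_edges = net.upper_triangle()
    point_cent = expected_influence(net).raw
    E = point_edges.size

    reps_e = np.full((n_boot, E), np.nan)
    reps_c = np.full((n_boot, p), np.nan)
    failed = 0
    for k in range(n_boot):
        rng = np.random.default_rng([seed, k])
        idx = rng.integers(0, n, size=n)
        try:
            bnet = fit_ggm(X[idx], config=config)
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            failed += 1
            continue
        reps_e[k] = bnet.upper_triangle()
        reps_c[k] = expected_influence(bnet).raw
    if failed > max_failure_rate * n_boot:
        raise RuntimeError(f"{failed}/{n_boot} bootstrap replicates failed")
    ok = ~np.isnan(reps_e).any(axis=1)
    lo = (1.0 - ci_level) / 2.0
    ci = np.column_stack(
        [
            np.quantile(reps_e[ok], lo, axis=0),
            np.quantile(reps_e[ok], 1.0 - lo, axis=0),
        ]
    )
    return ResamplingResult(
        nodes=nodes,
        point_edges=point_edges,
        point_centrality=point_cent,
        replicate_edges=reps_e[ok],
        replicate_centrality=reps_c[ok],
        edge_ci=ci,
        ci_level=ci_level,
        n_failed=failed,
        metric="EI",
    )


def difference_test(
    result: ResamplingResult, kind: str = "edge", alpha: float = 0.05
) -> np.ndarray:
    """Bootstrapped difference test between all pairs of edges or centralities.

    Pair (a, b) is flagged significant when the (1 - alpha) percentile
    interval of the bootstrap distribution of (value_a - value_b) excludes 0.
    No multiplicity correction is applied (the convention of the bootstrap
    stability framework).  Returns a symmetric boolean matrix with a False
    diagonal.
    """
    if kind == "edge":
        reps = result.replicate_edges
    elif kind == "centrality":
        reps = result.replicate_centrality
    else:
        raise ValueError("kind must be 'edge' or 'centrality'")
    if reps is None or len(reps) == 0:
        raise ValueError("replicate store is empty")
    m = reps.shape[1]
    lo, hi = alpha / 2.0, 1.0 - alpha / 2.0
    sig = np.zeros((m, m), dtype=bool)
    for a in range(m):
        diffs = reps[:, a][:, None] - reps  # (B, m)
        ql = np.quantile(diffs, lo, axis=0)
        qh = np.quantile(diffs, hi, axis=0)
        sig[a] = (ql > 0) | (qh < 0)
    np.fill_diagonal(sig, False)
    return sig | sig.T


def _centrality_for(data_or_pair, metric, config, folds, seed, n_alphas=100):
    if metric == "EI":
        return expected_influence(fit_ggm(data_or_pair, config=config)).raw
    net = zero_autoregressive(
        fit_clpn(data_or_pair, folds=folds, seed=seed, n_alphas=n_alphas)
    )
    iei, oei = in_out_expected_influence(net)
    return iei.raw if metric == "IEI" else oei.raw


def case_drop_cs(
    data,
    metric: str = "EI",
    wave=None,
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    n_boot: int = 100,
    seed: int = 0,
    config: GGMConfig = GGMConfig(),
    folds: int = 10,
    cor_threshold: float = 0.7,
    confidence: float = 0.95,
    n_alphas: int = 100,
) -> ResamplingResult:
    """Case-drop bootstrap and CS-coefficient for a centrality metric.

    For each drop proportion q, participants are subsampled without
    replacement to (1 - q) of the sample, the network is re-estimated, and
    the subsample centralities are correlated (Pearson) with the full-sample
    ones.  The CS-coefficient is the largest q at which at least
    ``confidence`` of replicates reach a correlation of ``cor_threshold``
    (0 when no grid point qualifies).  Values of 0.5 or higher indicate
    strong stability.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not all(0.0 < q < 1.0 for q in drop_grid):
        raise ValueError("drop proportions must be in (0, 1)")
    if metric not in ("EI", "IEI", "OEI"):
        raise ValueError("metric must be EI, IEI or OEI")

    if metric == "EI":
        X, nodes = _as_matrix(data, wave)
        n, p = X.shape
        full = _centrality_for(X, metric, config, folds, seed, n_alphas)
        subset_input = lambda idx: X[idx]
    else:
        if not isinstance(data, PanelDataset):
            raise TypeError("IEI/OEI stability requires a PanelDataset (both waves)")
        n, p = data.n, data.p
        nodes = data.schema.item_ids
        X1, X2 = wave_matrix(data, 0), wave_matrix(data, 1)
        full = _centrality_for((X1, X2), metric, config, folds, seed, n_alphas)
        subset_input = lambda idx: (X1[idx], X2[idx])

    curves: dict[float, np.ndarray] = {}
    for q in drop_grid:
        m = int(round(n * (1.0 - q)))
        if m < p:
            warnings.warn(
                f"drop proportion {q:.2f} leaves {m} < p={p} cases; grid point skipped"
            )
            continue
        cors = np.full(n_boot, np.nan)
        for k in range(n_boot):
            rng = np.random.default_rng([seed, int(round(q * 100)), k])
            idx = rng.choice(n, size=m, replace=False)
            try:
                sub = _centrality_for(subset_input(idx), metric, config, folds, seed,
                                      n_alphas)
            except (ConvergenceError, ValueError, np.linalg.LinAlgError):
                continue
            if np.std(sub) == 0 or np.std(full) == 0:
                continue
            cors[k] = np.corrcoef(full, sub)[0, 1]
        curves[float(q)] = cors

    cs = 0.0
    for q in sorted(curves):
        c = curves[q]
        ok = np.isfinite(c)
        if ok.sum() == 0:
            continue
        if np.mean(c[ok] >= cor_threshold) >= confidence:
            cs = max(cs, q)
    return ResamplingResult(
        nodes=nodes,
        point_centrality=full,
        cs_curves=curves,
        cs_coefficient=cs,
        metric=metric,
    )
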