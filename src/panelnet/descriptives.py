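"""Item- and scale-level descriptive statistics and effect sizes.

Reproduces the machinery behind a two-wave descriptive table: per-item mean,
SD, skewness and kurtosis at each wave, the total score (mean across items),
a paired t test of the change in total scores, Hedges' g with small-sample
correction, and Cronbach's alpha per wave.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import PanelDataset, wave_matrix

__all__ = [
    "DescriptivesTable",
    "EffectSizeResult",
    "item_descriptives",
    "paired_t_hedges",
    "cronbach_alpha",
]


@dataclass
class DescriptivesTable:
    """Per-item (plus total-score) mean/SD/skewness/kurtosis per wave."""

    table: pd.DataFrame  # index: item ids + "total"; columns: (wave, stat)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


@dataclass
class EffectSizeResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    hedges_g: float


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, sample SD, adjusted Fisher-Pearson skewness, adjusted excess
    kurtosis.  Degenerate (constant) input yields NaN shape statistics."""
    m = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        warnings.warn("constant column: skewness/kurtosis undefined")
        return m, sd, np.nan, np.nan
    skew = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    return m, sd, skew, kurt


def item_descriptives(data: PanelDataset) -> DescriptivesTable:
    """Mean, SD, skewness and kurtosis per item and wave, plus the total
    score (mean across all items, so the total-score mean equals the mean of
    item means)."""
    rows = {}
    for w, wave in enumerate(data.waves):
        X = wave_matrix(data, w)
        for j, item in enumerate(data.schema.item_ids):
            rows.setdefault(item, {}).update(
                dict(zip([(wave, s) for s in ("mean", "sd", "skew", "kurtosis")],
                         _moments(X[:, j])))
            )
        total = X.mean(axis=1)
        rows.setdefault("total", {}).update(
            dict(zip([(wave, s) for s in ("mean", "sd", "skew", "kurtosis")],
                     _moments(total)))
        )
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["wave", "stat"])
    df = df.reindex([*data.schema.item_ids, "total"])
    return DescriptivesTable(table=df)


def paired_t_hedges(data: PanelDataset, denominator: str = "pooled") -> EffectSizeResult:
    """Paired t test and Hedges' g for the change in total scores.

    The difference is follow-up minus baseline, so g is negative when
    symptoms decline.  g = (M2 - M1) / SD * J with the small-sample
    correction J = 1 - 3/(4 df - 1), df = n - 1.  ``denominator`` chooses the
    standardizer: "pooled" (default) uses sqrt((SD1^2 + SD2^2)/2), "baseline"
    the baseline SD.
    """
    t1 = wave_matrix(data, 0).mean(axis=1)
    t2 = wave_matrix(data, 1).mean(axis=1)
    n = len(t1)
    if n < 2:
        raise ValueError("need at least two participants")
    d = t2 - t1
    if np.std(d, ddof=1) == 0:
        if d[0] != 0:
            raise ValueError("zero variance of paired differences")
        t_stat, p = 0.0, 1.0  # identical waves
    else:
        t_stat, p = stats.ttest_rel(t2, t1)
    df = n - 1
    sd1, sd2 = np.std(t1, ddof=1), np.std(t2, ddof=1)
    if denominator == "pooled":
        sd = np.sqrt((sd1**2 + sd2**2) / 2.0)
    elif denominator == "baseline":
        sd = sd1
    else:
        raise ValueError("denominator must be 'pooled' or 'baseline'")
    if sd == 0:
        g = 0.0
    else:
        J = 1.0 - 3.0 / (4.0 * df - 1.0)
        g = float((t2.mean() - t1.mean()) / sd * J)
    return EffectSizeResult(
        t_statistic=float(t_stat), degrees_of_freedom=df, p_value=float(p), hedges_g=g
    )


def cronbach_alpha(data: PanelDataset, wave: str | int = 0) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / variance of
    the item-sum score)."""
    X = wave_matrix(data, wave)
    k = X.shape[1]
    if k < 2:
        raise ValueError("alpha needs at least two items")
    total_var = np.var(X.sum(axis=1), ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    item_var = np.var(X, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))
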