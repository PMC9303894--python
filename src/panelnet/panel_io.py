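"""Two-wave ordinal panel data: schema, container, CSV round-trip,
complete-case filtering, and single imputation by predictive mean matching.

The bundled :data:`IESR_SCHEMA` describes the 22-item Impact of Event
Scale-Revised (0-4 Likert responses) with its five subscales: six intrusion
items, six avoidance items, five hyperarousal items, two numbing items and
three sleep-disturbance items.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ItemSchema",
    "PanelDataset",
    "IESR_SCHEMA",
    "SchemaError",
    "ValidationError",
    "EmptyResultError",
    "read_panel_csv",
    "write_panel_csv",
    "read_schema_json",
    "write_schema_json",
    "complete_cases",
    "pmm_impute",
    "wave_matrix",
]

WAVES = ("baseline", "followup")


class SchemaError(ValueError):
    """A required column is absent or the schema itself is malformed."""


class ValidationError(ValueError):
    """A cell value violates the declared response range."""


class EmptyResultError(ValueError):
    """A filter removed every participant; downstream estimation undefined."""


@dataclass(frozen=True)
class ItemSchema:
    """Item labels, subscale membership and the shared response range."""

    item_ids: tuple[str, ...]
    subscale_of: dict[str, str]
    response_range: tuple[int, int] = (0, 4)

    def __post_init__(self):
        if len(set(self.item_ids)) != len(self.item_ids):
            raise SchemaError("duplicate item ids")
        for item in self.item_ids:
            if item not in self.subscale_of:
                raise SchemaError(f"item {item!r} has no subscale assignment")
        lo, hi = self.response_range
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer)) and lo < hi):
            raise SchemaError("response_range must be increasing integer bounds")

    @property
    def p(self) -> int:
        return len(self.item_ids)

    def subscale_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for item in self.item_ids:
            sizes[self.subscale_of[item]] = sizes.get(self.subscale_of[item], 0) + 1
        return sizes

    def subscale_index(self) -> np.ndarray:
        """Integer subscale code per item, in item order."""
        labels = list(dict.fromkeys(self.subscale_of[i] for i in self.item_ids))
        return np.array([labels.index(self.subscale_of[i]) for i in self.item_ids])


def _iesr_schema() -> ItemSchema:
    groups = {
        "intrusion": ["In1", "In2", "In3", "In4", "In5", "In6"],
        "avoidance": ["Av1", "Av2", "Av3", "Av4", "Av5", "Av6"],
        "hyperarousal": ["Ha1", "Ha2", "Ha3", "Ha4", "Ha5"],
        "numbing": ["Nb1", "Nb2"],
        "sleep": ["Sd1", "Sd2", "Sd3"],
    }
    items = [i for sub in groups.values() for i in sub]
    sub_of = {i: name for name, sub in groups.items() for i in sub}
    return ItemSchema(item_ids=tuple(items), subscale_of=sub_of, response_range=(0, 4))


IESR_SCHEMA = _iesr_schema()


@dataclass
class PanelDataset:
    """n participants x p items x 2 waves of ordinal responses.

    ``responses`` is float with NaN at missing cells; ``mask`` is True where
    a response is missing.  Non-missing entries are whole numbers within the
    schema's response range.
    """

    ids: np.ndarray
    responses: np.ndarray  # (n, p, 2) float, NaN at missing
    mask: np.ndarray  # (n, p, 2) bool, True = missing
    schema: ItemSchema
    waves: tuple[str, str] = WAVES

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.responses = np.asarray(self.responses, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, p, w = self.responses.shape
        if self.mask.shape != (n, p, w) or w != 2:
            raise ValidationError("responses and mask must both be (n, p, 2)")
        if p != self.schema.p:
            raise ValidationError(f"expected {self.schema.p} items, got {p}")
        if len(self.ids) != n:
            raise ValidationError("ids length does not match responses")
        if len(np.unique(self.ids)) != n:
            raise ValidationError("participant ids must be unique")
        if bool(np.isnan(self.responses[~self.mask]).any()):
            raise ValidationError("NaN response at a cell not flagged missing")
        obs = self.responses[~self.mask]
        lo, hi = self.schema.response_range
        if obs.size and (np.any(obs != np.round(obs)) or obs.min() < lo or obs.max() > hi):
            raise ValidationError(f"responses must be integers in [{lo}, {hi}]")
        self.responses[self.mask] = np.nan

    @property
    def n(self) -> int:
        return self.responses.shape[0]

    @property
    def p(self) -> int:
        return self.responses.shape[1]

    def n_missing(self) -> int:
        return int(self.mask.sum())

    def wave_index(self, wave: str | int) -> int:
        if isinstance(wave, (int, np.integer)):
            if wave not in (0, 1):
                raise ValueError("wave index must be 0 or 1")
            return int(wave)
        if wave not in self.waves:
            raise ValueError(f"unknown wave {wave!r}; expected one of {self.waves}")
        return self.waves.index(wave)

    def copy(self) -> "PanelDataset":
        return PanelDataset(
            ids=self.ids.copy(),
            responses=self.responses.copy(),
            mask=self.mask.copy(),
            schema=self.schema,
            waves=self.waves,
        )


def wave_matrix(data: PanelDataset, wave: str | int) -> np.ndarray:
    """The (n, p) score matrix of one wave; raises if any cell is missing."""
    w = data.wave_index(wave)
    X = data.responses[:, :, w]
    if np.isnan(X).any():
        raise ValidationError(
            "wave matrix contains missing values; apply complete_cases or pmm_impute first"
        )
    return X.copy()


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

DEFAULT_DIALECT = ("{item}_t1", "{item}_t2")


def _column_names(schema: ItemSchema, dialect: tuple[str, str]) -> tuple[list[str], list[str]]:
    c1 = [dialect[0].format(item=i) for i in schema.item_ids]
    c2 = [dialect[1].format(item=i) for i in schema.item_ids]
    return c1, c2


def read_panel_csv(
    path,
    schema: ItemSchema = IESR_SCHEMA,
    dialect: tuple[str, str] = DEFAULT_DIALECT,
    id_column: str = "id",
) -> PanelDataset:
    """Read a wide-format two-wave panel CSV.

    One row per participant; per item, two columns named by ``dialect``
    (default ``<item>_t1`` / ``<item>_t2``).  Empty cells become missing;
    non-integer or out-of-range values raise :class:`ValidationError` naming
    the offending row and column.
    """
    df = pd.read_csv(path)
    cols1, cols2 = _column_names(schema, dialect)
    for col in [id_column, *cols1, *cols2]:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    ids = df[id_column].to_numpy()
    n, p = len(df), schema.p
    responses = np.full((n, p, 2), np.nan)
    lo, hi = schema.response_range
    for w, cols in enumerate((cols1, cols2)):
        for j, col in enumerate(cols):
            raw = pd.to_numeric(df[col], errors="coerce")
            bad = raw.notna() & ((raw != np.round(raw)) | (raw < lo) | (raw > hi))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"value {df[col].iloc[row]!r} out of range [{lo}, {hi}] "
                    f"at row {row}, column {col!r}"
                )
            # distinguish a truly empty cell from a non-numeric token
            nonnum = df[col].notna() & raw.isna()
            if nonnum.any():
                row = int(np.flatnonzero(nonnum.to_numpy())[0])
                raise ValidationError(
                    f"non-numeric value {df[col].iloc[row]!r} at row {row}, column {col!r}"
                )
            responses[:, j, w] = raw.to_numpy()
    mask = np.isnan(responses)
    return PanelDataset(ids=ids, responses=responses, mask=mask, schema=schema)


def write_panel_csv(
    data: PanelDataset,
    path,
    dialect: tuple[str, str] = DEFAULT_DIALECT,
    id_column: str = "id",
) -> None:
    cols1, cols2 = _column_names(data.schema, dialect)
    out = {id_column: data.ids}
    for w, cols in enumerate((cols1, cols2)):
        for j, col in enumerate(cols):
            vals = data.responses[:, j, w]
            if np.isnan(vals).any():
                out[col] = pd.array(
                    [int(v) if not np.isnan(v) else pd.NA for v in vals], dtype="Int64"
                )
            else:
                out[col] = vals.astype(int)
    pd.DataFrame(out).to_csv(path, index=False)


def read_schema_json(path) -> ItemSchema:
    with open(path) as fh:
        obj = json.load(fh)
    return ItemSchema(
        item_ids=tuple(obj["item_ids"]),
        subscale_of=dict(obj["subscale_of"]),
        response_range=tuple(obj.get("response_range", (0, 4))),
    )


def write_schema_json(schema: ItemSchema, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "item_ids": list(schema.item_ids),
                "subscale_of": schema.subscale_of,
                "response_range": list(schema.response_range),
            },
            fh,
            indent=2,
        )


# ---------------------------------------------------------------------------
# Complete cases and predictive mean matching
# ---------------------------------------------------------------------------

def complete_cases(data: PanelDataset) -> PanelDataset:
    """Participants with no missing response at any item of either wave.

    Order is preserved.  Raises :class:`EmptyResultError` when nobody
    survives, since every estimator downstream requires data.
    """
    keep = ~data.mask.any(axis=(1, 2))
    if not keep.any():
        raise EmptyResultError("complete-case filter removed all participants")
    return PanelDataset(
        ids=data.ids[keep],
        responses=data.responses[keep],
        mask=data.mask[keep],
        schema=data.schema,
        waves=data.waves,
    )


def pmm_impute(
    data: PanelDataset,
    donors: int = 5,
    iterations: int = 5,
    seed: int = 0,
) -> PanelDataset:
    """Single imputation by predictive mean matching (chained equations).

    Columns (item x wave) are visited left to right.  For each incomplete
    column a linear regression on all other columns of both waves is fit on
    the observed rows; each missing cell receives the observed value of a
    donor drawn uniformly from the ``donors`` rows whose predicted means are
    closest to the missing cell's prediction.  Every imputed value is
    therefore an actually observed response of the same item.  Deterministic
    given ``seed``; only masked cells are ever modified.
    """
    rng = np.random.default_rng(seed)
    n, p, _ = data.responses.shape
    flat = data.responses.reshape(n, 2 * p, order="F").copy()  # columns: wave-major
    miss = data.mask.reshape(n, 2 * p, order="F")
    if not miss.any():
        return data.copy()
    if miss.all(axis=0).any():
        j = int(np.flatnonzero(miss.all(axis=0))[0])
        raise ValueError(f"column {j} entirely missing: no donors available")

    # initialize missing cells with random observed values of the same column
    for j in range(2 * p):
        mj = miss[:, j]
        if mj.any():
            obs = flat[~mj, j]
            flat[mj, j] = rng.choice(obs, size=mj.sum(), replace=True)

    incomplete = [j for j in range(2 * p) if miss[:, j].any()]
    for _ in range(iterations):
        for j in incomplete:
            mj = miss[:, j]
            X = np.delete(flat, j, axis=1)
            X = np.column_stack([np.ones(n), X])
            y = flat[:, j]
            coef, *_ = np.linalg.lstsq(X[~mj], y[~mj], rcond=None)
            pred = X @ coef
            pred_obs = pred[~mj]
            y_obs = data.responses.reshape(n, 2 * p, order="F")[~mj, j]
            order = np.argsort(pred_obs, kind="stable")
            sorted_pred, sorted_y = pred_obs[order], y_obs[order]
            k = min(donors, len(sorted_y))
            for row in np.flatnonzero(mj):
                pos = np.searchsorted(sorted_pred, pred[row])
                lo = max(0, min(pos - k // 2, len(sorted_y) - k))
                cand = np.arange(lo, lo + k)
                # refine: the k candidates nearest in predicted mean
                dists = np.abs(sorted_pred[cand] - pred[row])
                pick = cand[np.argsort(dists, kind="stable")][: k]
                flat[row, j] = sorted_y[rng.choice(pick)]

    responses = flat.reshape(n, p, 2, order="F")
    return PanelDataset(
        ids=data.ids.copy(),
        responses=responses,
        mask=np.zeros_like(data.mask),
        schema=data.schema,
        waves=data.waves,
    )
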