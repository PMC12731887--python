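"""Two-wave panel data: container, CSV I/O, scoring, missingness, descriptives.

A :class:`PanelDataset` holds one row per subject with 22 analysis variables
(11 subscale scores at discharge, T1, and 11 at the three-month follow-up,
T2), a covariate table (age plus categorical demographics), and a cancer
stage per subject.  Missing values are represented as NaN in ``values``; the
boolean missingness mask is derived from that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    DomainError,
    EmptyDataError,
    MappingError,
    SchemaError,
    ValidationError,
)
from .labels import (
    NODE_CODES,
    NODES,
    STAGES,
    T1_COLUMNS,
    T2_COLUMNS,
    t1_column,
    t2_column,
)

ANALYSIS_COLUMNS = T1_COLUMNS + T2_COLUMNS

#: Default CSV schema: column names for id, stage, covariates and subscales.
DEFAULT_SCHEMA: dict = {
    "id": "subject_id",
    "stage": "stage",
    "covariates": ["age", "education", "marital", "occupation", "income"],
    "t1": {code: t1_column(code) for code in NODE_CODES},
    "t2": {code: t2_column(code) for code in NODE_CODES},
}


@dataclass
class PanelDataset:
    """Subject x variable panel with covariates, stage and missingness mask.

    ``values`` columns are ``D1_T1 .. F7_T1, D1_T2 .. F7_T2`` in fixed node
    order; ``covariates`` may be empty; ``stage`` is one of I/II/III/IV for
    every subject.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame
    stage: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ANALYSIS_COLUMNS if c not in self.values.columns]
        if missing:
            raise SchemaError(f"missing analysis columns: {missing}")
        self.values = self.values[list(ANALYSIS_COLUMNS)].astype(float)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate subject id: {dup!r}")
        if not self.stage.index.equals(self.values.index):
            raise ValidationError("stage index does not match values index")
        bad_stage = set(self.stage.dropna().unique()) - set(STAGES)
        if bad_stage:
            raise ValidationError(f"unknown stage codes: {sorted(bad_stage)}")
        if self.stage.isna().any():
            raise ValidationError("stage missing for some subjects")
        if (self.values < 0).any().any():
            raise ValidationError("subscale scores must be non-negative")
        if len(self.covariates) and not self.covariates.index.equals(
            self.values.index
        ):
            raise ValidationError("covariate index does not match values index")

    @property
    def subjects(self) -> int:
        return len(self.values)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """True where a value is absent."""
        return self.values.isna()

    def t1(self) -> pd.DataFrame:
        return self.values[list(T1_COLUMNS)]

    def t2(self) -> pd.DataFrame:
        return self.values[list(T2_COLUMNS)]

    def select(self, index) -> "PanelDataset":
        """Row subset (or resample, when ``index`` repeats positions)."""
        idx = np.asarray(index)
        vals = self.values.iloc[idx].reset_index(drop=True)
        cov = (
            self.covariates.iloc[idx].reset_index(drop=True)
            if len(self.covariates)
            else self.covariates
        )
        stage = self.stage.iloc[idx].reset_index(drop=True)
        return PanelDataset(vals, cov, stage, dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        """Single flat table (covariates + stage + analysis variables)."""
        parts = []
        if len(self.covariates):
            parts.append(self.covariates)
        parts.append(self.stage.rename("stage").to_frame())
        parts.append(self.values)
        return pd.concat(parts, axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="subject_id")


def read_panel(path, schema: Mapping | None = None) -> PanelDataset:
    """Read a one-row-per-subject CSV into a validated :class:`PanelDataset`.

    ``schema`` maps logical roles to column names (see
    :data:`DEFAULT_SCHEMA`); unparseable numeric cells become missing values.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    raw = pd.read_csv(path)

    required = [sch["stage"]]
    required += [sch["t1"][c] for c in NODE_CODES]
    required += [sch["t2"][c] for c in NODE_CODES]
    for col in required:
        if col not in raw.columns:
            raise SchemaError(f"required column missing from CSV: {col!r}")

    if sch["id"] in raw.columns:
        ids = raw[sch["id"]]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate subject id: {dup!r}")
        raw = raw.set_index(sch["id"])

    values = pd.DataFrame(index=raw.index)
    for code in NODE_CODES:
        values[t1_column(code)] = pd.to_numeric(
            raw[sch["t1"][code]], errors="coerce"
        )
        values[t2_column(code)] = pd.to_numeric(
            raw[sch["t2"][code]], errors="coerce"
        )

    cov_cols = [c for c in sch.get("covariates", []) if c in raw.columns]
    covariates = raw[cov_cols].copy() if cov_cols else pd.DataFrame(index=raw.index)
    stage = raw[sch["stage"]].astype(str).str.strip()
    return PanelDataset(values, covariates, stage)


# ---------------------------------------------------------------------------
# item-level scaffolding


def score_items(items: pd.DataFrame, item_map: Mapping[str, str]) -> pd.DataFrame:
    """Sum item responses into subscale scores (one wave).

    ``item_map`` maps every item column to a subscale code; an unmapped
    column raises :class:`MappingError`.
    """
    unmapped = [c for c in items.columns if c not in item_map]
    if unmapped:
        raise MappingError(f"items not mapped to any subscale: {unmapped}")
    bad = {c: s for c, s in item_map.items() if s not in NODE_CODES}
    if bad:
        raise MappingError(f"unknown subscale codes in map: {bad}")
    out = pd.DataFrame(index=items.index)
    for code in NODE_CODES:
        cols = [c for c in items.columns if item_map[c] == code]
        if cols:
            out[code] = items[cols].sum(axis=1)
    return out


def score_subscales(
    items: pd.DataFrame,
    item_map: Mapping[str, str],
    stage: pd.Series | None = None,
    covariates: pd.DataFrame | None = None,
) -> PanelDataset:
    """Build a :class:`PanelDataset` from item-level responses of both waves.

    ``items`` columns are named ``<item>_T1`` / ``<item>_T2``; ``item_map``
    maps the bare item name to its subscale code.  Subscale score = sum of
    its items (higher = more of the construct).
    """
    t1_cols = [c for c in items.columns if c.endswith("_T1")]
    t2_cols = [c for c in items.columns if c.endswith("_T2")]
    if not t1_cols or not t2_cols:
        raise SchemaError("item table needs *_T1 and *_T2 columns")

    def _wave(cols: list[str], suffix: str) -> pd.DataFrame:
        bare = {c: c[: -len(suffix)] for c in cols}
        missing = [b for b in bare.values() if b not in item_map]
        if missing:
            raise MappingError(f"items not mapped to any subscale: {missing}")
        wave_map = {c: item_map[bare[c]] for c in cols}
        return score_items(items[cols], wave_map)

    s1 = _wave(t1_cols, "_T1")
    s2 = _wave(t2_cols, "_T2")
    values = pd.DataFrame(index=items.index)
    for code in NODE_CODES:
        values[t1_column(code)] = s1.get(code, 0.0)
        values[t2_column(code)] = s2.get(code, 0.0)
    if stage is None:
        stage = pd.Series("I", index=items.index)
    if covariates is None:
        covariates = pd.DataFrame(index=items.index)
    return PanelDataset(values, covariates, stage)


def da_present(total_da_score) -> bool | np.ndarray:
    """Death anxiety screening cut-off: present iff the DAS total is >= 7."""
    score = np.asarray(total_da_score, dtype=float)
    if np.any(score < 0):
        raise DomainError("DAS total score cannot be negative")
    result = score >= 7.0
    return bool(result) if result.ndim == 0 else result


# ---------------------------------------------------------------------------
# missing data


@dataclass(frozen=True)
class ListwiseResult:
    """Complete-case subset plus retention bookkeeping."""

    data: PanelDataset
    n_input: int
    n_retained: int

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_retained

    @property
    def retention(self) -> float:
        return self.n_retained / self.n_input

    @property
    def retention_pct(self) -> float:
        return 100.0 * self.retention


def listwise_complete(data: PanelDataset) -> ListwiseResult:
    """Keep only subjects with no missing analysis variable (listwise
    deletion), reporting the retention fraction."""
    complete = ~data.missing_mask.any(axis=1)
    n_keep = int(complete.sum())
    if n_keep == 0:
        raise EmptyDataError("no subject has complete analysis variables")
    kept = data.select(np.flatnonzero(complete.to_numpy()))
    return ListwiseResult(kept, data.subjects, n_keep)


# ---------------------------------------------------------------------------
# descriptives


def descriptives(data: PanelDataset) -> pd.DataFrame:
    """Per-subscale mean and sample SD (ddof=1) per wave, over observed
    values; layout mirrors the package's printed-table fixture."""
    rows = []
    for node in NODES:
        a = data.values[t1_column(node.code)]
        b = data.values[t2_column(node.code)]
        rows.append(
            {
                "code": node.code,
                "label": node.name,
                "t1_mean": a.mean(),
                "t1_sd": a.std(ddof=1),
                "t2_mean": b.mean(),
                "t2_sd": b.std(ddof=1),
            }
        )
    return pd.DataFrame(rows).set_index("code")


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / total
    variance).  Requires at least two items."""
    k = items.shape[1]
    if k < 2:
        raise DomainError("Cronbach's alpha needs at least 2 items")
    item_var = items.var(axis=0, ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DomainError("total score has zero variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))
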