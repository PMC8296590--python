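"""NICHD development-stage model and the pediatric safety-report table.

A safety report is one row of the pediatric report universe: an opaque
``report_id``, an age in years, the NICHD child-development stage that age
falls in, and binary indicators for whether the drug and the event of
interest were reported.  Every disproportionality statistic downstream is
computed on tables of this shape, stratified by stage.

The seven NICHD stages partition the pediatric age range (0, 21] years.
The exact day/month cutoffs are configurable; the defaults follow NICHD
pediatric terminology with lower-exclusive / upper-inclusive intervals so
that age 21 is retained and age 0 excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StageDefinition",
    "NICHD_STAGES",
    "STAGE_NAMES",
    "ContingencyTable",
    "assign_stage",
    "pediatric_filter",
    "stage_contingency",
    "read_report_table",
    "write_report_table",
]

DAYS_PER_YEAR = 365.25

#: Required columns of a report table.
REPORT_COLUMNS = ["report_id", "age_years", "nichd_stage", "drug", "event"]


@dataclass(frozen=True)
class StageDefinition:
    """One NICHD stage: a named, ordered age interval ``(age_lo, age_hi]`` in years."""

    name: str
    index: int
    age_lo: float
    age_hi: float

    def contains(self, age_years: float) -> bool:
        return self.age_lo < age_years <= self.age_hi


def _default_stages() -> tuple[StageDefinition, ...]:
    cut = [0.0, 27 / DAYS_PER_YEAR, 1.0, 2.0, 5.0, 11.0, 18.0, 21.0]
    names = [
        "term_neonatal",
        "infancy",
        "toddler",
        "early_childhood",
        "middle_childhood",
        "early_adolescence",
        "late_adolescence",
    ]
    return tuple(
        StageDefinition(name=n, index=i + 1, age_lo=cut[i], age_hi=cut[i + 1])
        for i, n in enumerate(names)
    )


#: Default NICHD stage table: contiguous, non-overlapping, covering (0, 21].
NICHD_STAGES: tuple[StageDefinition, ...] = _default_stages()
STAGE_NAMES: tuple[str, ...] = tuple(s.name for s in NICHD_STAGES)
STAGE_INDEX: dict[str, int] = {s.name: s.index for s in NICHD_STAGES}

AGE_MAX = NICHD_STAGES[-1].age_hi


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug-by-event report counts for one stratum.

    ``a`` drug & event, ``b`` event without drug, ``c`` drug without event,
    ``d`` neither; ``a+b+c+d`` is the stratum size.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def assign_stage(
    age_years: float, stages: Sequence[StageDefinition] = NICHD_STAGES
) -> str:
    """Return the name of the unique stage whose interval contains ``age_years``.

    Raises ``ValueError`` for ages outside the pediatric range (callers are
    expected to have applied :func:`pediatric_filter` already).
    """
    if not np.isfinite(age_years) or age_years <= stages[0].age_lo or age_years > stages[-1].age_hi:
        raise ValueError(
            f"age {age_years!r} outside the pediatric range "
            f"({stages[0].age_lo}, {stages[-1].age_hi}]"
        )
    for s in stages:
        if s.contains(age_years):
            return s.name
    raise ValueError(f"no stage covers age {age_years!r}")  # pragma: no cover


def assign_stage_vector(
    age_years: np.ndarray, stages: Sequence[StageDefinition] = NICHD_STAGES
) -> np.ndarray:
    """Vectorized :func:`assign_stage` for ages already inside (0, 21]."""
    edges = np.array([s.age_lo for s in stages] + [stages[-1].age_hi])
    # side="left" makes intervals lower-exclusive / upper-inclusive
    idx = np.searchsorted(edges, np.asarray(age_years, dtype=float), side="left") - 1
    if (idx < 0).any() or (idx >= len(stages)).any():
        bad = np.asarray(age_years)[(idx < 0) | (idx >= len(stages))][:5]
        raise ValueError(f"ages outside pediatric range, e.g. {bad}")
    names = np.array([s.name for s in stages])
    return names[idx]


def pediatric_filter(
    raw: pd.DataFrame,
    stages: Sequence[StageDefinition] = NICHD_STAGES,
    age_column: str = "age_years",
    unit_column: str | None = None,
) -> pd.DataFrame:
    """Keep reports with 0 < age <= 21 years and assign NICHD stages.

    Rows with a missing or non-numeric age are dropped (count logged).  If
    ``unit_column`` is given, per-row unit codes convert ages to years first:
    ``YR`` (years, as-is), ``MON`` (months of a 365.25-day year), ``DY``
    (days), ``WK`` (weeks), ``DEC`` (decades), ``HR`` (hours).
    """
    df = raw.copy()
    age = pd.to_numeric(df[age_column], errors="coerce")
    if unit_column is not None:
        factor = {
            "YR": 1.0,
            "MON": 1.0 / 12.0,
            "WK": 7.0 / DAYS_PER_YEAR,
            "DY": 1.0 / DAYS_PER_YEAR,
            "HR": 1.0 / (24.0 * DAYS_PER_YEAR),
            "DEC": 10.0,
        }
        units = df[unit_column].astype(str).str.upper().map(factor)
        age = age * units
    n_bad = int(age.isna().sum())
    if n_bad:
        logger.info("pediatric_filter: dropped %d rows with missing/invalid age", n_bad)
    lo, hi = stages[0].age_lo, stages[-1].age_hi
    keep = age.notna() & (age > lo) & (age <= hi)
    out = df.loc[keep].copy()
    out["age_years"] = age.loc[keep].astype(float)
    out["nichd_stage"] = assign_stage_vector(out["age_years"].to_numpy(), stages)
    return out.reset_index(drop=True)


def stage_contingency(table: pd.DataFrame, stage: str) -> ContingencyTable:
    """2x2 drug-by-event counts over the reports of one NICHD stage."""
    if stage not in STAGE_INDEX:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGE_NAMES}")
    sub = table.loc[table["nichd_stage"] == stage]
    drug = sub["drug"].to_numpy(dtype=bool)
    event = sub["event"].to_numpy(dtype=bool)
    a = int((drug & event).sum())
    c = int((drug & ~event).sum())
    b = int((~drug & event).sum())
    d = int((~drug & ~event).sum())
    return ContingencyTable(a=a, b=b, c=c, d=d)


def stage_count_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Per-stage a/b/c/d counts for all 7 stages at once (vectorized).

    Returns a frame indexed by stage name in NICHD order with columns
    ``a, b, c, d``; stages absent from the table get all-zero rows.
    """
    stage = pd.Categorical(table["nichd_stage"], categories=STAGE_NAMES)
    drug = table["drug"].to_numpy(dtype=np.int64)
    event = table["event"].to_numpy(dtype=np.int64)
    cell = drug * 2 + event  # 3=a, 1=b, 2=c, 0=d
    counts = pd.crosstab(stage, cell, dropna=False).reindex(
        index=STAGE_NAMES, columns=[3, 1, 2, 0], fill_value=0
    )
    counts.columns = ["a", "b", "c", "d"]
    counts.index.name = "nichd_stage"
    return counts.astype(np.int64)


def validate_report_table(table: pd.DataFrame) -> None:
    missing = [c for c in REPORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"report table missing required column(s): {missing}")
    if table["report_id"].duplicated().any():
        raise ValueError("report_id values must be unique")


def read_report_table(path, stages: Sequence[StageDefinition] = NICHD_STAGES) -> pd.DataFrame:
    """Read a report table from delimited CSV (or parquet by extension).

    Columns ``report_id, age_years, drug, event`` are required; an
    ``age_unit`` column triggers unit conversion; ``nichd_stage`` is
    recomputed from age if absent.
    """
    path = str(path)
    if path.endswith((".parquet", ".pq")):
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    required = ["report_id", "drug", "event"]
    age_ok = "age_years" in df.columns or {"age", "age_unit"} <= set(df.columns)
    missing = [c for c in required if c not in df.columns]
    if missing or not age_ok:
        if not age_ok:
            missing.append("age_years")
        raise ValueError(f"report table file missing required column(s): {missing}")
    if "age_years" not in df.columns:
        df = pediatric_filter(df, stages, age_column="age", unit_column="age_unit")
    elif "nichd_stage" not in df.columns:
        df = pediatric_filter(df, stages)
    df["drug"] = df["drug"].astype(np.int8)
    df["event"] = df["event"].astype(np.int8)
    validate_report_table(df)
    return df[REPORT_COLUMNS + [c for c in df.columns if c not in REPORT_COLUMNS]]


def write_report_table(table: pd.DataFrame, path) -> None:
    """Write a report table as CSV (or parquet by extension). Lossless round-trip."""
    validate_report_table(table)
    path = str(path)
    if path.endswith((".parquet", ".pq")):
        table.to_parquet(path, index=False)
    else:
        table.to_csv(path, index=False)
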