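"""Positive / negative control construction and class-vs-uniform contrasts.

Positive control pairs are augmented under *all five* dynamics classes
(each with its own freshly drawn fold change), producing one
(drug-event, stage, dynamics) triple per stage per class.  Negative
control pairs are left bit-identical to their generated tables.  Seeds
are derived from the master seed by stable hashing of (pair id, class),
so any single augmented dataset is reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    DYNAMICS_CLASSES,
    DynamicsSpec,
    InfeasibleEffectError,
    inject_events,
    sample_fold_change,
)
from .generate import PairSpec
from .stages import STAGE_NAMES
from .util import seed_for

logger = logging.getLogger(__name__)

__all__ = ["ControlRecord", "build_controls", "class_vs_uniform_contrast"]

MAX_FC_REDRAWS = 20


@dataclass
class ControlRecord:
    """One control dataset: a pair, its set label, and (for positives) the
    dynamics spec under which its table was augmented."""

    pair: PairSpec
    set_label: str  # "positive" | "negative"
    dynamics_class: str | None
    spec: DynamicsSpec | None
    table: pd.DataFrame

    @property
    def pair_id(self) -> str:
        return self.pair.pair_id


def _base_event_rate(table: pd.DataFrame) -> float:
    """Event reporting rate among non-drug reports (the comparator rate)."""
    non_drug = table.loc[table["drug"] == 0, "event"]
    if len(non_drug) == 0:
        raise ValueError("table has no non-drug reports; base rate undefined")
    rate = float(non_drug.mean())
    if rate <= 0.0:
        # multiplicative effects need a nonzero baseline; use half a count
        rate = 0.5 / len(non_drug)
        logger.info("zero baseline event rate; flooring at %.3g", rate)
    return min(rate, 1.0 - 1e-9)


def drug_reports_per_stage(table: pd.DataFrame) -> np.ndarray:
    counts = table.loc[table["drug"] == 1, "nichd_stage"].value_counts()
    return np.array([int(counts.get(s, 0)) for s in STAGE_NAMES])


def build_controls(
    pair_tables: Iterable[tuple[PairSpec, pd.DataFrame]],
    positive_ids: set[str],
    negative_ids: set[str],
    fc_rate: float = 0.75,
    seed: int = 0,
    classes: Sequence[str] = DYNAMICS_CLASSES,
    **curve_kwargs,
) -> Iterator[ControlRecord]:
    """Yield control datasets: 5 class-augmented tables per positive pair,
    untouched tables for negatives.

    An infeasible fold change (target mean rate above 1) is logged and
    redrawn from the same distribution.
    """
    if positive_ids & negative_ids:
        raise ValueError("positive and negative pair sets must be disjoint")
    for pair, table in pair_tables:
        if pair.pair_id in negative_ids:
            yield ControlRecord(pair, "negative", None, None, table)
            continue
        if pair.pair_id not in positive_ids:
            continue
        base_rate = _base_event_rate(table)
        n_drug = drug_reports_per_stage(table)
        if n_drug.sum() == 0:
            logger.warning("positive pair %s has no drug reports; skipped", pair.pair_id)
            continue
        for cls in classes:
            cls_seed = seed_for(seed, "augment", pair.pair_id, cls)
            rng = np.random.default_rng(cls_seed)
            spec = None
            for attempt in range(MAX_FC_REDRAWS):
                fc = sample_fold_change(fc_rate, rng)
                try:
                    spec = DynamicsSpec.solve(
                        cls, fc, base_rate, n_drug, seed=cls_seed, **curve_kwargs
                    )
                    break
                except InfeasibleEffectError as err:
                    logger.info(
                        "pair %s class %s: FC %.3g infeasible (%s); redrawing",
                        pair.pair_id, cls, fc, err,
                    )
            if spec is None:
                logger.warning(
                    "pair %s class %s: no feasible fold change after %d draws; skipped",
                    pair.pair_id, cls, MAX_FC_REDRAWS,
                )
                continue
            augmented = inject_events(table, spec, seed=seed_for(cls_seed, "inject"))
            yield ControlRecord(pair, "positive", cls, spec, augmented)


def class_vs_uniform_contrast(
    scores: pd.DataFrame,
    value_col: str = "value",
    n_resamples: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-stage mean score difference of each dynamics class vs uniform.

    ``scores`` is long-format with columns ``pair_id, dynamics_class,
    nichd_stage`` and ``value_col``.  Pairs are resampled with replacement
    ``n_resamples`` times; each resample contributes the difference of the
    class and uniform stage means over the *same* resampled pairs, and the
    summary is the mean difference with a 95% percentile interval.
    Non-finite scores (NaN / infinite PRRs) are excluded from the means.
    """
    if "uniform" not in set(scores["dynamics_class"]):
        raise ValueError("scores must include the uniform reference class")
    rng = np.random.default_rng(seed)
    uniform = scores[scores["dynamics_class"] == "uniform"]
    rows = []
    for cls, cls_scores in scores.groupby("dynamics_class", sort=False):
        if cls == "uniform":
            continue
        pair_ids = np.array(sorted(set(cls_scores["pair_id"]) & set(uniform["pair_id"])))
        if pair_ids.size < 2:
            raise ValueError(f"class {cls!r}: need >= 2 pairs shared with uniform")
        c_wide = cls_scores.pivot_table(
            index="pair_id", columns="nichd_stage", values=value_col, aggfunc="mean"
        ).reindex(index=pair_ids, columns=STAGE_NAMES)
        u_wide = uniform.pivot_table(
            index="pair_id", columns="nichd_stage", values=value_col, aggfunc="mean"
        ).reindex(index=pair_ids, columns=STAGE_NAMES)
        c_arr = c_wide.to_numpy(dtype=float)
        u_arr = u_wide.to_numpy(dtype=float)
        c_arr[~np.isfinite(c_arr)] = np.nan
        u_arr[~np.isfinite(u_arr)] = np.nan
        diffs = np.empty((n_resamples, len(STAGE_NAMES)))
        for i in range(n_resamples):
            take = rng.integers(0, pair_ids.size, size=pair_ids.size)
            with np.errstate(all="ignore"):
                diffs[i] = np.nanmean(c_arr[take], axis=0) - np.nanmean(u_arr[take], axis=0)
        mean = np.nanmean(diffs, axis=0)
        lo = np.nanpercentile(diffs, 2.5, axis=0)
        hi = np.nanpercentile(diffs, 97.5, axis=0)
        for j, stage in enumerate(STAGE_NAMES):
            rows.append(
                {
                    "dynamics_class": cls,
                    "nichd_stage": stage,
                    "mean_diff": float(mean[j]),
                    "ci_lo": float(lo[j]),
                    "ci_hi": float(hi[j]),
                    "n_pairs": int(pair_ids.size),
                }
            )
    return pd.DataFrame(rows)
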