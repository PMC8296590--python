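"""Power-calibrated reference-standard construction.

A method can only be scored fairly on pairs whose data it could plausibly
detect.  For each (method, score type, dynamics class) the power analysis
finds the region of data characteristics — minimum per-stage drug-report
count n and minimum fold change FC — in which at least ``t`` = 80% of the
injected triples score above the method's null threshold, *restricted to
the class's high-reporting stages* (stages where the class actually
injects signal; low-reporting stages produce spurious scores and are
dropped).  Triples at or beyond the chosen (n, FC) frontier become the
positive instances of that class's reference standard; the negatives are
every (negative pair, stage) double, identical across classes.  The
uniform class defines no reference standard of its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stages import STAGE_NAMES

__all__ = [
    "HIGH_REPORTING_STAGES",
    "high_reporting_stages",
    "compute_power_grid",
    "select_frontier",
    "build_reference",
    "ReferenceStandard",
]

#: Default per-class high-reporting stage masks, derived from the weight-curve
#: geometry: the stages where each class's injection weight is near its peak.
HIGH_REPORTING_STAGES: dict[str, tuple[str, ...]] = {
    "uniform": STAGE_NAMES,
    "increase": ("early_adolescence", "late_adolescence"),
    "decrease": ("term_neonatal", "infancy"),
    "plateau": ("early_childhood", "middle_childhood"),
    "inverse_plateau": ("term_neonatal", "late_adolescence"),
}


def high_reporting_stages(
    dynamics_class: str, masks: dict[str, tuple[str, ...]] | None = None
) -> tuple[str, ...]:
    """Stages at which the class injects near-peak signal (config-overridable)."""
    masks = masks or HIGH_REPORTING_STAGES
    if dynamics_class not in masks:
        raise ValueError(f"unknown dynamics class {dynamics_class!r}")
    return tuple(masks[dynamics_class])


def compute_power_grid(
    triples: pd.DataFrame,
    threshold: float,
    value_col: str = "value",
    n_grid: int = 10,
) -> pd.DataFrame:
    """Power over a grid of (min drug reports, min fold change) cutoffs.

    ``triples`` must carry ``n_drug`` (drug reports at the triple's stage),
    ``fold_change`` and the score column; it should already be restricted
    to high-reporting stages.  Grid cutoffs are deciles of the observed
    n_drug and fold-change distributions.  Power at a grid point is the
    fraction of triples meeting both cutoffs whose score strictly exceeds
    the threshold; NaN scores never count as detections.  Empty cells get
    power = NaN.
    """
    if triples.empty:
        raise ValueError("no triples supplied to the power analysis")
    n_drug = triples["n_drug"].to_numpy(dtype=float)
    fc = triples["fold_change"].to_numpy(dtype=float)
    vals = triples[value_col].to_numpy(dtype=float)
    above = np.zeros(vals.shape, dtype=bool)
    finite_or_inf = ~np.isnan(vals)
    above[finite_or_inf] = vals[finite_or_inf] > threshold

    qs = np.linspace(0, 0.9, n_grid)
    n_cuts = np.unique(np.quantile(n_drug, qs))
    fc_cuts = np.unique(np.quantile(fc, qs))
    rows = []
    for n0 in n_cuts:
        sel_n = n_drug >= n0
        for f0 in fc_cuts:
            sel = sel_n & (fc >= f0)
            m = int(sel.sum())
            rows.append(
                {
                    "n_min": float(n0),
                    "fc_min": float(f0),
                    "n_triples": m,
                    "power": float(above[sel].mean()) if m else np.nan,
                }
            )
    return pd.DataFrame(rows)


def select_frontier(grid: pd.DataFrame, t: float = 0.80) -> pd.Series | None:
    """The qualifying grid point: power >= t, maximizing triple count,
    ties broken toward smaller n then smaller FC.  None if no point reaches t."""
    ok = grid[(grid["power"] >= t) & (grid["n_triples"] > 0)]
    if ok.empty:
        return None
    ok = ok.sort_values(
        ["n_triples", "n_min", "fc_min"], ascending=[False, True, True]
    )
    return ok.iloc[0]


@dataclass
class ReferenceStandard:
    """Labeled instances for one dynamics class.

    ``positives``: (pair_id, nichd_stage) plus per-(method, score type)
    qualification flags and the frontier each came from.  ``negatives``:
    every (negative pair, stage) double.
    """

    dynamics_class: str
    positives: pd.DataFrame
    negatives: pd.DataFrame
    frontiers: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        pos = self.positives[["pair_id", "nichd_stage"]].copy()
        pos["label"] = 1
        neg = self.negatives[["pair_id", "nichd_stage"]].copy()
        neg["label"] = 0
        out = pd.concat([pos, neg], ignore_index=True)
        out.insert(0, "dynamics_class", self.dynamics_class)
        return out


def build_reference(
    positive_scores: pd.DataFrame,
    negative_pair_ids,
    t: float = 0.80,
    thresholds: dict[str, float] | None = None,
    masks: dict[str, tuple[str, ...]] | None = None,
    n_grid: int = 10,
) -> dict[str, ReferenceStandard]:
    """One reference standard per non-uniform dynamics class.

    ``positive_scores`` is long-format over the augmented positive triples:
    columns ``pair_id, dynamics_class, nichd_stage, method, score_type,
    value, n_drug, fold_change``.  For each class, each (method, score
    type) contributes the triples at or beyond its own >= t-power frontier;
    the class's positive set is their union, with per-method flags kept so
    the origin of each positive is auditable.
    """
    from .detectors import GAM_NULL, PRR_NULL

    thresholds = thresholds or {"PRR": PRR_NULL, "GAM": GAM_NULL}
    standards: dict[str, ReferenceStandard] = {}
    negatives = pd.DataFrame(
        [(p, s) for p in negative_pair_ids for s in STAGE_NAMES],
        columns=["pair_id", "nichd_stage"],
    )
    for cls in sorted(set(positive_scores["dynamics_class"])):
        if cls == "uniform":
            continue
        stages = high_reporting_stages(cls, masks)
        cls_scores = positive_scores[
            (positive_scores["dynamics_class"] == cls)
            & (positive_scores["nichd_stage"].isin(stages))
        ]
        qualified: dict[str, set[tuple[str, str]]] = {}
        frontier_rows = []
        for (method, score_type), sub in cls_scores.groupby(["method", "score_type"]):
            grid = compute_power_grid(sub, thresholds[method], n_grid=n_grid)
            frontier = select_frontier(grid, t)
            key = f"{method}_{score_type}"
            if frontier is None:
                qualified[key] = set()
                frontier_rows.append(
                    {"method": method, "score_type": score_type,
                     "n_min": np.nan, "fc_min": np.nan, "power": np.nan}
                )
                continue
            sel = sub[
                (sub["n_drug"] >= frontier["n_min"])
                & (sub["fold_change"] >= frontier["fc_min"])
            ]
            qualified[key] = set(zip(sel["pair_id"], sel["nichd_stage"]))
            frontier_rows.append(
                {"method": method, "score_type": score_type,
                 "n_min": float(frontier["n_min"]), "fc_min": float(frontier["fc_min"]),
                 "power": float(frontier["power"])}
            )
        union = sorted(set().union(*qualified.values())) if qualified else []
        pos = pd.DataFrame(union, columns=["pair_id", "nichd_stage"])
        for key, members in qualified.items():
            pos[f"qualifies_{key}"] = [
                (p, s) in members for p, s in zip(pos["pair_id"], pos["nichd_stage"])
            ] if len(pos) else pd.Series(dtype=bool)
        standards[cls] = ReferenceStandard(
            dynamics_class=cls,
            positives=pos,
            negatives=negatives,
            frontiers=pd.DataFrame(frontier_rows),
        )
    return standards
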