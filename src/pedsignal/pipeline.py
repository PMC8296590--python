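"""End-to-end study orchestration.

Chains the pipeline: synthetic report generation, control sampling,
dynamics augmentation, dual-method scoring, power-calibrated reference
construction, and performance evaluation.  Every stochastic step derives
its seed deterministically from the master seed, so identical configs
produce bit-identical outputs and any intermediate table can be
regenerated on demand (which is how the removal sensitivity analysis
re-obtains tables without storing them).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .augment import ControlRecord, build_controls, drug_reports_per_stage
from .detectors import GAM_NULL, PRR_NULL, gam_by_stage, prr_by_stage
from .dynamics import DEFAULT_CENTER, DEFAULT_PLATEAU_CENTERS, DEFAULT_STEEPNESS, FC_MAX, FC_RATE
from .evaluate import UndefinedMetricError, performance_report
from .generate import (
    DEFAULT_STAGE_WEIGHTS,
    GeneratorConfig,
    default_catalog,
    generate_reports,
    sample_control_pairs,
)
from .power import ReferenceStandard, build_reference
from .stages import STAGE_NAMES
from .util import seed_for

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StudyResult", "score_record", "run_study", "run_removal"]

THRESHOLDS = {"PRR": PRR_NULL, "GAM": GAM_NULL}


@dataclass
class RunConfig:
    """Declarative configuration of a full simulation-and-evaluation run.

    Defaults are the desk-scale study conditions: a 50,000-report
    universe, 50 positive and 500 negative control pairs from a
    600-pair catalog, fold changes from 1 + Exp(0.75) truncated at 10,
    80% power calibration, 100 bootstrap resamples.
    """

    n_reports: int = 50_000
    stage_weights: Sequence[float] = DEFAULT_STAGE_WEIGHTS
    catalog_size: int = 600
    n_pos: int = 50
    n_neg: int = 500
    p_drug_range: tuple[float, float] = (0.005, 0.05)
    p_event_range: tuple[float, float] = (0.005, 0.05)
    fc_rate: float = FC_RATE
    fc_max: float = FC_MAX
    steepness: float = DEFAULT_STEEPNESS
    center: float = DEFAULT_CENTER
    plateau_centers: tuple[float, float] = DEFAULT_PLATEAU_CENTERS
    z_lower: float = 1.2816
    power_t: float = 0.80
    n_boot: int = 100
    n_resample: int = 20
    removal_fractions: Sequence[float] = tuple(np.round(np.arange(0, 1.01, 0.1), 1))
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        for key in ("p_drug_range", "p_event_range", "plateau_centers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["stage_weights"] = list(self.stage_weights)
        d["removal_fractions"] = list(self.removal_fractions)
        for key in ("p_drug_range", "p_event_range", "plateau_centers"):
            d[key] = list(d[key])
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class StudyResult:
    """All frames produced by a run.

    ``scores``: long format, one row per (pair, dynamics class, method,
    score type, stage) with value, quality and the triple's metadata
    (per-stage drug report count, fold change).  ``references``: one
    power-calibrated standard per non-uniform class.  ``performance``:
    the evaluation grid.
    """

    config: RunConfig
    scores: pd.DataFrame
    assignment: pd.DataFrame
    references: dict[str, ReferenceStandard] = field(default_factory=dict)
    performance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(out / "scores.csv", index=False)
        self.assignment.to_csv(out / "assignment.csv", index=False)
        if self.references:
            pd.concat([r.to_frame() for r in self.references.values()]).to_csv(
                out / "reference_standards.csv", index=False
            )
        if len(self.performance):
            self.performance.to_csv(out / "performance.csv", index=False)
        manifest = {
            "config": json.loads(self.config.to_json()),
            "n_score_rows": int(len(self.scores)),
            "n_pairs_scored": int(self.scores["pair_id"].nunique()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def score_record(record: ControlRecord, z_lower: float = 1.2816) -> pd.DataFrame:
    """Both methods' per-stage scores for one control dataset, long format."""
    prr_sc = prr_by_stage(record.table, record.pair_id, z_lower=z_lower)
    gam_sc = gam_by_stage(record.table, record.pair_id, z_lower=z_lower)
    sc = pd.concat([prr_sc, gam_sc], ignore_index=True)
    sc["set_label"] = record.set_label
    sc["dynamics_class"] = record.dynamics_class if record.dynamics_class else ""
    sc["fold_change"] = record.spec.fold_change if record.spec else np.nan
    n_drug = drug_reports_per_stage(record.table)
    sc["n_drug"] = sc["nichd_stage"].map(dict(zip(STAGE_NAMES, n_drug)))
    return sc


def _control_stream(config: RunConfig) -> Iterator[ControlRecord]:
    catalog = default_catalog(
        config.catalog_size,
        seed_for(config.seed, "catalog"),
        config.p_drug_range,
        config.p_event_range,
    )
    pos, neg = sample_control_pairs(
        catalog, config.n_pos, config.n_neg, seed_for(config.seed, "controls")
    )
    gen = GeneratorConfig(
        n_reports=config.n_reports,
        stage_weights=config.stage_weights,
        pair_catalog=pos + neg,
        seed=config.seed,
    )
    yield from build_controls(
        generate_reports(gen),
        positive_ids={p.pair_id for p in pos},
        negative_ids={p.pair_id for p in neg},
        fc_rate=config.fc_rate,
        seed=config.seed,
        steepness=config.steepness,
        center=config.center,
        plateau_centers=config.plateau_centers,
    )


def run_study(config: RunConfig, evaluate: bool = True) -> StudyResult:
    """Run the pipeline end to end and return all result frames."""
    score_frames, assign_rows = [], []
    for record in _control_stream(config):
        score_frames.append(score_record(record, z_lower=config.z_lower))
        assign_rows.append(
            {
                "pair_id": record.pair_id,
                "set_label": record.set_label,
                "dynamics_class": record.dynamics_class or "",
                "fold_change": record.spec.fold_change if record.spec else np.nan,
                "spec_json": record.spec.to_json() if record.spec else "",
            }
        )
    scores = pd.concat(score_frames, ignore_index=True)
    assignment = pd.DataFrame(assign_rows)
    result = StudyResult(config=config, scores=scores, assignment=assignment)
    if not evaluate:
        return result

    long = melt_score_types(scores)
    pos_long = long[long["set_label"] == "positive"]
    neg_long = long[long["set_label"] == "negative"]
    neg_ids = sorted(set(neg_long["pair_id"]))
    result.references = build_reference(
        pos_long, neg_ids, t=config.power_t, thresholds=THRESHOLDS
    )
    result.performance = evaluate_references(
        result.references, pos_long, neg_long, config
    )
    return result


def melt_score_types(scores: pd.DataFrame) -> pd.DataFrame:
    """Widen-to-long over the two score types ('score' and '90mse')."""
    keep = [c for c in scores.columns if c not in ("score", "lower90", "se")]
    a = scores[keep].copy()
    a["score_type"] = "score"
    a["value"] = scores["score"].to_numpy()
    b = scores[keep].copy()
    b["score_type"] = "90mse"
    b["value"] = scores["lower90"].to_numpy()
    return pd.concat([a, b], ignore_index=True)


def evaluate_references(
    references: dict[str, ReferenceStandard],
    pos_long: pd.DataFrame,
    neg_long: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Per (dynamics class, method, score type) performance with bootstrap CIs."""
    rows = []
    for cls, ref in references.items():
        pos_keys = set(zip(ref.positives["pair_id"], ref.positives["nichd_stage"]))
        cls_scores = pos_long[pos_long["dynamics_class"] == cls]
        for (method, score_type), sub in cls_scores.groupby(["method", "score_type"]):
            in_ref = sub[
                [k in pos_keys for k in zip(sub["pair_id"], sub["nichd_stage"])]
            ]
            neg = neg_long[
                (neg_long["method"] == method) & (neg_long["score_type"] == score_type)
            ]
            base = {
                "dynamics_class": cls,
                "method": method,
                "score_type": score_type,
            }
            if in_ref.empty:
                logger.warning("reference %s has no positives for %s/%s", cls, method, score_type)
                rows.append({**base, "auroc": np.nan, "n_pos": 0, "n_neg": len(neg)})
                continue
            try:
                rep = performance_report(
                    in_ref["value"],
                    neg["value"],
                    THRESHOLDS[method],
                    n_boot=config.n_boot,
                    seed=seed_for(config.seed, "perf", cls, method, score_type),
                )
            except UndefinedMetricError:
                rep = {"auroc": np.nan, "n_pos": len(in_ref), "n_neg": len(neg)}
            rows.append({**base, **rep})
    return pd.DataFrame(rows)


def run_removal(
    config: RunConfig,
    references: dict[str, ReferenceStandard],
    stage: str,
    fractions: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Drug-report-removal sensitivity analysis at one stage.

    Control tables are regenerated from the config's seeds (bit-identical
    to the original run), reduced, rescored with both methods, and
    evaluated at the reduced stage against the reference standards.
    """
    from .evaluate import removal_sensitivity

    fractions = list(config.removal_fractions if fractions is None else fractions)
    pos_frames = []
    for cls, ref in references.items():
        p = ref.positives[["pair_id", "nichd_stage"]].copy()
        p["dynamics_class"] = cls
        pos_frames.append(p)
    reference_positives = pd.concat(pos_frames, ignore_index=True)
    neg_ids = set(references[next(iter(references))].negatives["pair_id"])

    def record_iter():
        for record in _control_stream(config):
            yield record.pair_id, record.dynamics_class or "", record.table

    scorers = {
        "PRR": lambda t: prr_by_stage(t, z_lower=config.z_lower),
        "GAM": lambda t: gam_by_stage(t, z_lower=config.z_lower),
    }
    return removal_sensitivity(
        record_iter,
        scorers,
        reference_positives,
        neg_ids,
        stage,
        fractions,
        THRESHOLDS,
        seed=config.seed,
        n_boot=config.n_boot,
    )
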