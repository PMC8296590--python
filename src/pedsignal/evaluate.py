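"""Detection-performance evaluation: AUROC, threshold metrics, bootstrap
CIs, low-reporting and drug-removal sensitivity analyses, and the
real-world reference-set protocol.

Score-handling policy (this moves AUROC, so exclusion counts are always
reported): NaN-quality scores are excluded from ranking and from
threshold calls; zero scores are kept; +infinity ranks above every finite
score and always calls positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_chisquare

from .stages import STAGE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedMetricError",
    "auroc",
    "threshold_metrics",
    "bootstrap_ci",
    "performance_report",
    "low_reporting_performance",
    "remove_drug_reports",
    "removal_sensitivity",
    "read_grip_reference",
    "real_world_validation",
]


class UndefinedMetricError(ValueError):
    """A metric's defining sets are empty (e.g. after NaN exclusion)."""


def _clean(x) -> tuple[np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    keep = ~np.isnan(x)
    return x[keep], int((~keep).sum())


def auroc(pos_scores, neg_scores) -> float:
    """P(random positive score > random negative score); ties count 1/2.

    Rank-based (Mann-Whitney U / (n_pos * n_neg)).  NaN scores are
    excluded (counts logged); +inf ranks above all finite scores.
    """
    pos, n_ex_p = _clean(pos_scores)
    neg, n_ex_n = _clean(neg_scores)
    if n_ex_p or n_ex_n:
        logger.debug("auroc: excluded %d positive, %d negative NaN scores", n_ex_p, n_ex_n)
    if pos.size == 0 or neg.size == 0:
        raise UndefinedMetricError("AUROC undefined: a score set is empty after NaN exclusion")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def threshold_metrics(pos_scores, neg_scores, threshold: float) -> dict[str, float]:
    """Sensitivity, PPV and NPV at a score threshold.

    A score calls positive iff strictly greater than the threshold and
    negative iff at or below it.  PPV (NPV) is NaN when no instance is
    predicted positive (negative).
    """
    pos, _ = _clean(pos_scores)
    neg, _ = _clean(neg_scores)
    if pos.size == 0 or neg.size == 0:
        raise UndefinedMetricError("threshold metrics undefined: empty score set")
    tp = float((pos > threshold).sum())
    fn = float((pos <= threshold).sum())
    fp = float((neg > threshold).sum())
    tn = float((neg <= threshold).sum())
    sens = tp / (tp + fn)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    return {"sensitivity": sens, "ppv": ppv, "npv": npv}


def bootstrap_ci(
    metric_fn,
    pos_scores,
    neg_scores,
    n_boot: int = 100,
    seed: int = 0,
    ci: float = 95.0,
) -> tuple[float, float, float]:
    """Percentile bootstrap interval for a two-sample score metric.

    Positive and negative sets are resampled independently with
    replacement; a resample on which the metric is undefined is redrawn
    (count logged).  Returns (point, lo, hi).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    pos, _ = _clean(pos_scores)
    neg, _ = _clean(neg_scores)
    point = metric_fn(pos, neg)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    n_redraw = 0
    for i in range(n_boot):
        for _ in range(100):
            p = rng.choice(pos, size=pos.size, replace=True)
            n = rng.choice(neg, size=neg.size, replace=True)
            try:
                vals[i] = metric_fn(p, n)
                break
            except UndefinedMetricError:
                n_redraw += 1
        else:  # pragma: no cover - essentially impossible with nonempty inputs
            vals[i] = np.nan
    if n_redraw:
        logger.debug("bootstrap_ci: %d degenerate resamples redrawn", n_redraw)
    alpha = (100.0 - ci) / 2.0
    lo, hi = np.nanpercentile(vals, [alpha, 100.0 - alpha])
    return float(point), float(lo), float(hi)


def performance_report(
    pos_scores,
    neg_scores,
    threshold: float,
    n_boot: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """AUROC + threshold metrics, each with a 95% bootstrap interval."""
    out: dict[str, float] = {}
    pos, n_ex_p = _clean(pos_scores)
    neg, n_ex_n = _clean(neg_scores)
    out["n_pos"], out["n_neg"] = pos.size, neg.size
    out["n_excluded_pos"], out["n_excluded_neg"] = n_ex_p, n_ex_n
    for name, fn in [
        ("auroc", auroc),
        ("sensitivity", lambda p, n: threshold_metrics(p, n, threshold)["sensitivity"]),
        ("ppv", lambda p, n: threshold_metrics(p, n, threshold)["ppv"]),
        ("npv", lambda p, n: threshold_metrics(p, n, threshold)["npv"]),
    ]:
        point, lo, hi = bootstrap_ci(fn, pos, neg, n_boot=n_boot, seed=seed)
        out[name], out[f"{name}_lo"], out[f"{name}_hi"] = point, lo, hi
    return out


def low_reporting_performance(
    pos_triples: pd.DataFrame,
    neg_doubles: pd.DataFrame,
    threshold: float,
    bins,
    value_col: str = "value",
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Performance within bins of per-stage drug-report counts.

    Both frames need ``n_drug`` and the score column.  Bins are
    (lo, hi] intervals from the given edges; empty or one-class bins are
    skipped with a log message.
    """
    edges = np.asarray(bins, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        p = pos_triples[(pos_triples["n_drug"] > lo) & (pos_triples["n_drug"] <= hi)]
        n = neg_doubles[(neg_doubles["n_drug"] > lo) & (neg_doubles["n_drug"] <= hi)]
        if p.empty or n.empty:
            logger.info("low_reporting bin (%g, %g]: skipped (pos=%d, neg=%d)", lo, hi, len(p), len(n))
            continue
        try:
            rep = performance_report(
                p[value_col], n[value_col], threshold, n_boot=n_boot, seed=seed
            )
        except UndefinedMetricError:
            logger.info("low_reporting bin (%g, %g]: metrics undefined", lo, hi)
            continue
        rows.append({"n_drug_lo": lo, "n_drug_hi": hi, **rep})
    return pd.DataFrame(rows)


def remove_drug_reports(
    table: pd.DataFrame, stage: str, fraction: float, seed: int = 0
) -> pd.DataFrame:
    """Drop a uniform random fraction of drug-exposed reports at one stage.

    Removal is without replacement over the drug = 1 rows of the stage;
    other rows are untouched, so the event-reporting (comparator) rate is
    maintained while drug reporting becomes rarer.  fraction 0 is the
    identity; fraction 1 removes every drug report at the stage.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if stage not in STAGE_NAMES:
        raise ValueError(f"unknown stage {stage!r}")
    if fraction == 0.0:
        return table.copy()
    idx = table.index[(table["nichd_stage"] == stage) & (table["drug"] == 1)]
    k = int(round(fraction * len(idx)))
    if fraction == 1.0:
        k = len(idx)
    rng = np.random.default_rng(seed)
    drop = rng.choice(idx, size=k, replace=False) if k else []
    return table.drop(index=drop).reset_index(drop=True)


def removal_sensitivity(
    record_iter,
    scorers: dict[str, callable],
    reference_positives: pd.DataFrame,
    negative_ids: set[str],
    stage: str,
    fractions,
    thresholds: dict[str, float],
    seed: int = 0,
    n_boot: int = 100,
) -> pd.DataFrame:
    """Rescore all control tables after drug-report removal at one stage.

    ``record_iter`` is a callable returning an iterator of
    (pair_id, dynamics_class_or_None, table); ``scorers`` maps method name
    to a ``scorer(table) -> DataFrame`` (long per-stage scores with
    ``score`` and ``lower90`` columns).  For each removal fraction, each
    table has the fraction of its drug reports at ``stage`` removed
    (reseeded per (stage, fraction, pair)), is rescored, and performance
    at that stage is computed: reference positives at that stage vs every
    negative double at that same reduced stage.
    """
    from .util import seed_for

    pos_keys = set(
        zip(reference_positives["pair_id"], reference_positives.get("dynamics_class",
            pd.Series(["" for _ in range(len(reference_positives))])),
            reference_positives["nichd_stage"])
    )
    rows = []
    for fraction in fractions:
        stage_scores: dict[str, dict[str, list[float]]] = {
            m: {"pos_score": [], "pos_lower90": [], "neg_score": [], "neg_lower90": []}
            for m in scorers
        }
        for pair_id, cls, table in record_iter():
            rem_seed = seed_for(seed, "removal", stage, fraction, pair_id, cls)
            reduced = remove_drug_reports(table, stage, fraction, seed=rem_seed)
            for method, scorer in scorers.items():
                sc = scorer(reduced)
                at_stage = sc[sc["nichd_stage"] == stage]
                if at_stage.empty:
                    continue
                srow = at_stage.iloc[0]
                if pair_id in negative_ids:
                    stage_scores[method]["neg_score"].append(srow["score"])
                    stage_scores[method]["neg_lower90"].append(srow["lower90"])
                elif (pair_id, cls, stage) in pos_keys or (pair_id, "", stage) in pos_keys:
                    stage_scores[method]["pos_score"].append(srow["score"])
                    stage_scores[method]["pos_lower90"].append(srow["lower90"])
        for method, buckets in stage_scores.items():
            for score_type, (pk, nk) in {
                "score": ("pos_score", "neg_score"),
                "90mse": ("pos_lower90", "neg_lower90"),
            }.items():
                pos, neg = buckets[pk], buckets[nk]
                base = {
                    "nichd_stage": stage,
                    "fraction": fraction,
                    "method": method,
                    "score_type": score_type,
                }
                if not pos or not neg:
                    rows.append({**base, "auroc": np.nan, "n_pos": len(pos), "n_neg": len(neg)})
                    continue
                try:
                    rep = performance_report(
                        pos, neg, thresholds[method], n_boot=n_boot,
                        seed=seed_for(seed, "removal-boot", stage, fraction, method, score_type),
                    )
                except UndefinedMetricError:
                    rep = {"auroc": np.nan, "n_pos": len(pos), "n_neg": len(neg)}
                rows.append({**base, **rep})
    return pd.DataFrame(rows)


# -- real-world reference-set protocol --------------------------------------


def read_grip_reference(path) -> pd.DataFrame:
    """Read a pediatric ADE reference set CSV (GRiP layout).

    Requires a drug column (ATC id), an event column (MedDRA id) and a
    ``Control`` flag column; positives are rows with Control == 'C'.
    Column names are matched case-insensitively against common variants.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}

    def find(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise ValueError(f"reference set missing a column like {names}")

    drug_col = find("atc_concept_id", "atc", "drug_id", "drug")
    event_col = find("meddra_concept_id", "meddra", "event_id", "event")
    control_col = find("control", "control_flag")
    out = pd.DataFrame(
        {
            "drug_id": df[drug_col].astype(str),
            "event_id": df[event_col].astype(str),
            "control": df[control_col].astype(str),
        }
    )
    out["pair_id"] = out["drug_id"] + "|" + out["event_id"]
    return out


def real_world_validation(
    scores: pd.DataFrame,
    reference: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    pair_reduction: str = "max",
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Pair-level validation against a curated reference set.

    ``scores``: long per-stage scores (pair_id, method, nichd_stage,
    score, lower90, quality) over a corpus that covers the reference
    pairs; positives are reference rows with control == 'C', negatives
    the scored pairs complementary to the reference set (the caller's
    cross-product corpus).  A pair's prediction is the max (or mean) of
    its per-stage scores.

    Returns (performance frame, per-pair quality/significance tally frame,
    two-proportion test between methods on the fraction of pairs with a
    lower bound above the null in >= 1 stage).
    """
    from .detectors import GAM_NULL, PRR_NULL, QUALITY_CLASSES

    thresholds = thresholds or {"PRR": PRR_NULL, "GAM": GAM_NULL}
    if pair_reduction not in ("max", "mean"):
        raise ValueError("pair_reduction must be 'max' or 'mean'")
    reduce = np.nanmax if pair_reduction == "max" else np.nanmean

    pos_ids = set(reference.loc[reference["control"] == "C", "pair_id"])
    scored_ids = set(scores["pair_id"])
    missing = pos_ids - scored_ids
    if missing:
        logger.info("real_world_validation: %d reference pairs absent from corpus", len(missing))
    pos_ids &= scored_ids
    ref_ids = set(reference["pair_id"])
    neg_ids = scored_ids - ref_ids

    perf_rows, tally_rows = [], []
    sig_counts: dict[str, tuple[int, int]] = {}
    for method, msc in scores.groupby("method", sort=False):
        thr = thresholds[method]
        for score_type, col in [("score", "score"), ("90mse", "lower90")]:
            with np.errstate(all="ignore"):
                pair_vals = msc.groupby("pair_id")[col].agg(
                    lambda v: reduce(v.to_numpy(dtype=float))
                    if np.isfinite(v.to_numpy(dtype=float)).any() or np.isinf(v.to_numpy(dtype=float)).any()
                    else np.nan
                )
            pos = pair_vals.reindex(sorted(pos_ids)).to_numpy(dtype=float)
            neg = pair_vals.reindex(sorted(neg_ids)).to_numpy(dtype=float)
            rep = performance_report(pos, neg, thr, n_boot=n_boot, seed=seed)
            perf_rows.append({"method": method, "score_type": score_type, **rep})
        # Table-2-style tally over reference-positive pairs
        ref_sc = msc[msc["pair_id"].isin(pos_ids)]
        tally = {"method": method, "n_pairs": len(pos_ids)}
        for q in QUALITY_CLASSES:
            tally[f"{q}_in_any_stage"] = int(
                ref_sc[ref_sc["quality"] == q]["pair_id"].nunique()
            )
        above = ref_sc[ref_sc["score"] > thr]["pair_id"].nunique()
        sig = ref_sc[ref_sc["lower90"] > thr]["pair_id"].nunique()
        tally["score_above_null"] = int(above)
        tally["lower90_above_null"] = int(sig)
        tally_rows.append(tally)
        sig_counts[method] = (sig, len(pos_ids))

    prop_test: dict[str, float] = {}
    if len(sig_counts) == 2:
        (c1, n1), (c2, n2) = sig_counts.values()
        stat, p, _ = proportions_chisquare([c1, c2], [n1, n2])
        prop_test = {"chi2": float(stat), "pvalue": float(p)}
    return pd.DataFrame(perf_rows), pd.DataFrame(tally_rows), prop_test
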