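"""ADE risk scorers: stage-stratified PRR and the stage-smooth GAM.

Both methods score one drug-event pair at each of the 7 NICHD stages and
report two score types: the point estimate (``score``) and a one-sided 90%
lower confidence bound (``lower90``, the more conservative score type).

The proportional reporting ratio for one stage's 2x2 table is

    PRR = (a / (a + c)) / (b / (b + d))

with a = drug & event, b = event without drug, c = drug without event,
d = neither.  Stratification makes the PRR fragile when data are thin, so
every score carries a quality class:

- ``nan``      — incomputable: the drug was never reported at the stage
                 (a + c = 0);
- ``infinite`` — the event was reported only with the drug (b = 0, a > 0);
- ``zero``     — the drug was never reported with the event (a = 0);
- ``finite``   — a positive, finite ratio.

GAM scores, by contrast, are always finite (the penalty interpolates
stages with no drug reports from their neighbours).

The null value is 1 for the PRR (ratio scale) and 0 for the GAM
(log-odds scale).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .gam import StageGAM
from .stages import ContingencyTable, STAGE_NAMES, stage_count_frame

__all__ = [
    "Z_LOWER_90",
    "PRR_NULL",
    "GAM_NULL",
    "QUALITY_CLASSES",
    "prr",
    "prr_by_stage",
    "StratifiedPRR",
    "gam_by_stage",
    "normality_summary",
]

#: One-sided 90% normal quantile for the lower-bound score type.
Z_LOWER_90 = 1.2816
#: Two-sided-90% alternative (config switch).
Z_LOWER_90_TWOSIDED = 1.645

PRR_NULL = 1.0
GAM_NULL = 0.0

QUALITY_CLASSES = ("zero", "nan", "finite", "infinite")

SCORE_COLUMNS = ["pair_id", "method", "nichd_stage", "score", "se", "lower90", "quality"]


def prr(ct: ContingencyTable, z_lower: float = Z_LOWER_90) -> tuple[float, float, str]:
    """PRR point score, lower bound and quality class for one 2x2 table.

    The lower bound uses the asymptotic variance of log PRR,
    1/a - 1/(a+c) + 1/b - 1/(b+d), and is only defined for finite nonzero
    scores; degenerate tables inherit their score's quality.
    """
    a, b, c, d = ct.a, ct.b, ct.c, ct.d
    if a + c == 0:
        return float("nan"), float("nan"), "nan"
    if a == 0:
        return 0.0, 0.0, "zero"
    if b == 0:
        return float("inf"), float("inf"), "infinite"
    score = (a / (a + c)) / (b / (b + d))
    var_log = 1.0 / a - 1.0 / (a + c) + 1.0 / b - 1.0 / (b + d)
    lower = float(np.exp(np.log(score) - z_lower * np.sqrt(max(var_log, 0.0))))
    return float(score), lower, "finite"


def _prr_frame(counts: pd.DataFrame, z_lower: float) -> pd.DataFrame:
    """Vectorized per-stage PRR over a stage x (a,b,c,d) count frame."""
    a = counts["a"].to_numpy(float)
    b = counts["b"].to_numpy(float)
    c = counts["c"].to_numpy(float)
    d = counts["d"].to_numpy(float)
    score = np.full(len(counts), np.nan)
    lower = np.full(len(counts), np.nan)
    quality = np.full(len(counts), "nan", dtype=object)
    zero = (a + c > 0) & (a == 0)
    infinite = (a + c > 0) & (a > 0) & (b == 0)
    finite = (a + c > 0) & (a > 0) & (b > 0)
    score[zero], lower[zero], quality[zero] = 0.0, 0.0, "zero"
    score[infinite], lower[infinite], quality[infinite] = np.inf, np.inf, "infinite"
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (a / (a + c)) / (b / (b + d))
        v = 1.0 / a - 1.0 / (a + c) + 1.0 / b - 1.0 / (b + d)
        lo = np.exp(np.log(s) - z_lower * np.sqrt(np.maximum(v, 0.0)))
    score[finite] = s[finite]
    lower[finite] = lo[finite]
    quality[finite] = "finite"
    se = np.where(finite, np.sqrt(np.maximum(v, 0.0)), np.nan)  # SE of log PRR
    return pd.DataFrame(
        {
            "nichd_stage": counts.index,
            "score": score,
            "se": se,
            "lower90": lower,
            "quality": quality,
        }
    ).reset_index(drop=True)


class StratifiedPRR(BaseEstimator):
    """Stage-stratified PRR as a fit/score estimator.

    ``fit`` takes per-report (stage, drug) and the binary event indicator,
    builds the seven 2x2 tables, and stores per-stage scores.  No
    information is shared across stages.

    Parameters
    ----------
    z_lower : float, default 1.2816
        Normal quantile of the one-sided lower confidence bound.

    Attributes
    ----------
    scores_ : DataFrame with per-stage score, se (of log PRR), lower90
        and quality class.
    counts_ : DataFrame of the seven a/b/c/d tables.
    """

    def __init__(self, z_lower: float = Z_LOWER_90):
        self.z_lower = z_lower

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            df = pd.DataFrame(
                {"nichd_stage": X["nichd_stage"].to_numpy(), "drug": X["drug"].to_numpy()}
            )
        else:
            arr = np.asarray(X)
            names = np.array(STAGE_NAMES)
            df = pd.DataFrame(
                {"nichd_stage": names[arr[:, 0].astype(int) - 1], "drug": arr[:, 1].astype(int)}
            )
        df["event"] = np.asarray(y, dtype=int)
        self.counts_ = stage_count_frame(df)
        self.scores_ = _prr_frame(self.counts_, self.z_lower)
        return self

    def fit_table(self, table: pd.DataFrame) -> "StratifiedPRR":
        return self.fit(table[["nichd_stage", "drug"]], table["event"].to_numpy())

    def stage_scores(self) -> pd.DataFrame:
        check_is_fitted(self, "scores_")
        return self.scores_.copy()


def prr_by_stage(
    table: pd.DataFrame, pair_id: str | None = None, z_lower: float = Z_LOWER_90
) -> pd.DataFrame:
    """Seven per-stage PRR scores for one pair's report table (long format)."""
    est = StratifiedPRR(z_lower=z_lower).fit_table(table)
    out = est.stage_scores()
    out.insert(0, "method", "PRR")
    out.insert(0, "pair_id", pair_id if pair_id is not None else table.attrs.get("pair_id", ""))
    return out[SCORE_COLUMNS]


def gam_by_stage(
    table: pd.DataFrame,
    pair_id: str | None = None,
    z_lower: float = Z_LOWER_90,
    **gam_params,
) -> pd.DataFrame:
    """Seven per-stage GAM scores for one pair's report table (long format)."""
    est = StageGAM(**gam_params).fit_table(table)
    out = est.stage_scores(z_lower=z_lower)
    out["quality"] = "finite"
    out.insert(0, "method", "GAM")
    out.insert(0, "pair_id", pair_id if pair_id is not None else table.attrs.get("pair_id", ""))
    return out[SCORE_COLUMNS]


def normality_summary(
    scores: pd.DataFrame,
    n_boot: int = 100,
    seed: int = 0,
    value_columns: tuple[str, ...] = ("score", "lower90"),
) -> pd.DataFrame:
    """Shapiro-Wilk normality profile of score distributions, per stage.

    For each (method, score type, stage) cell the pair scores are
    bootstrap-resampled ``n_boot`` times and the Shapiro-Wilk p-value
    computed on each resample; the cell reports the mean p-value with a
    95% percentile interval.  PRR scores are log10-transformed first, and
    zero / NaN / infinite scores are excluded with their fractions
    reported (the score-quality tally).  Cells with fewer than 3 usable
    scores, or essentially constant ones, are marked not assessable.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (method, stage), cell in scores.groupby(["method", "nichd_stage"], sort=False):
        for col in value_columns:
            vals = cell[col].to_numpy(dtype=float)
            n_total = vals.size
            frac = {
                q: float((cell["quality"] == q).mean()) if "quality" in cell else 0.0
                for q in QUALITY_CLASSES
            }
            if method == "PRR":
                usable = vals[np.isfinite(vals) & (vals > 0)]
                usable = np.log10(usable)
            else:
                usable = vals[np.isfinite(vals)]
            row = {
                "method": method,
                "score_type": "score" if col == "score" else "90mse",
                "nichd_stage": stage,
                "n_scores": n_total,
                "n_usable": int(usable.size),
                **{f"frac_{q}": frac[q] for q in QUALITY_CLASSES},
            }
            if usable.size < 3 or np.ptp(usable) < 1e-12:
                row.update(assessable=False, shapiro_p_mean=np.nan, shapiro_p_lo=np.nan, shapiro_p_hi=np.nan)
            else:
                pvals = np.empty(n_boot)
                for i in range(n_boot):
                    res = rng.choice(usable, size=usable.size, replace=True)
                    if np.ptp(res) < 1e-12:
                        pvals[i] = np.nan
                        continue
                    with np.errstate(all="ignore"):
                        pvals[i] = stats.shapiro(res).pvalue
                pvals = pvals[np.isfinite(pvals)]
                lo, hi = np.percentile(pvals, [2.5, 97.5])
                row.update(
                    assessable=True,
                    shapiro_p_mean=float(pvals.mean()),
                    shapiro_p_lo=float(lo),
                    shapiro_p_hi=float(hi),
                )
            rows.append(row)
    return pd.DataFrame(rows)
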