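"""Synthetic pediatric report-universe generator.

Emulates the marginal structure of pediatric spontaneous-report data (a
FAERS-like corpus) at configurable scale: a fixed universe of reports with
ages spread over the seven NICHD stages, and, for each drug-event pair in a
catalog, independent Bernoulli drug and event indicators.  Baseline
generation carries *no* drug-event association, so un-augmented pairs are
true negative controls; dynamic associations are added afterwards by the
injection step.

Every statistic downstream is stage-level, so ages are drawn uniformly
within each stage's interval; the stage mix itself is a configurable
weight vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stages import NICHD_STAGES, STAGE_NAMES
from .util import seed_for

__all__ = [
    "PairSpec",
    "GeneratorConfig",
    "default_catalog",
    "generate_universe",
    "generate_pair_table",
    "generate_reports",
    "sample_control_pairs",
    "reporting_summary",
]

#: Default stage mix: sparse neonatal reporting, heavier adolescence —
#: a plausible pediatric spontaneous-reporting profile.
DEFAULT_STAGE_WEIGHTS = (0.03, 0.12, 0.08, 0.12, 0.20, 0.25, 0.20)


@dataclass(frozen=True)
class PairSpec:
    """One drug-event pair: opaque concept ids plus marginal reporting rates."""

    drug_id: str
    event_id: str
    p_drug: float
    p_event: float

    @property
    def pair_id(self) -> str:
        return f"{self.drug_id}|{self.event_id}"


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic report universe.

    ``n_reports`` is the universe size; ``stage_weights`` the 7-vector of
    stage proportions (normalized on use); ``pair_catalog`` the drug-event
    pairs to emit tables for; ``seed`` drives all randomness.
    """

    n_reports: int = 50_000
    stage_weights: Sequence[float] = DEFAULT_STAGE_WEIGHTS
    pair_catalog: list[PairSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        w = np.asarray(self.stage_weights, dtype=float)
        if w.shape != (7,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("stage_weights must be 7 nonnegative values, not all zero")
        for p in self.pair_catalog:
            if not (0 <= p.p_drug <= 1 and 0 <= p.p_event <= 1):
                raise ValueError(f"pair {p.pair_id}: probabilities must be in [0, 1]")


def default_catalog(
    n_pairs: int,
    seed: int,
    p_drug_range: tuple[float, float] = (0.005, 0.05),
    p_event_range: tuple[float, float] = (0.005, 0.05),
) -> list[PairSpec]:
    """Catalog of pairs with log-uniform marginal drug/event reporting rates.

    Log-uniform marginals mimic the highly skewed reporting frequencies of
    real drugs and events, while keeping per-stage counts large enough that
    a stratified 2x2 analysis is usually (not always) computable.
    """
    rng = np.random.default_rng(seed)
    lo_d, hi_d = p_drug_range
    lo_e, hi_e = p_event_range
    p_drug = np.exp(rng.uniform(np.log(lo_d), np.log(hi_d), size=n_pairs))
    p_event = np.exp(rng.uniform(np.log(lo_e), np.log(hi_e), size=n_pairs))
    return [
        PairSpec(f"D{i:05d}", f"E{i:05d}", float(p_drug[i]), float(p_event[i]))
        for i in range(n_pairs)
    ]


def generate_universe(
    n_reports: int, stage_weights: Sequence[float], seed: int
) -> pd.DataFrame:
    """The shared report universe: report ids, ages, and NICHD stages.

    Stage membership is multinomial in ``stage_weights``; ages are uniform
    within each stage's (lo, hi] interval.
    """
    w = np.asarray(stage_weights, dtype=float)
    if w.shape != (7,) or (w < 0).any() or w.sum() <= 0:
        raise ValueError("stage_weights must be 7 nonnegative values, not all zero")
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    stage_idx = rng.choice(7, size=n_reports, p=w)
    lo = np.array([s.age_lo for s in NICHD_STAGES])
    hi = np.array([s.age_hi for s in NICHD_STAGES])
    u = rng.uniform(size=n_reports)
    # uniform on (lo, hi]: complement of u keeps the upper endpoint reachable
    age = hi[stage_idx] - u * (hi[stage_idx] - lo[stage_idx])
    names = np.array(STAGE_NAMES)
    return pd.DataFrame(
        {
            "report_id": [f"R{i:07d}" for i in range(n_reports)],
            "age_years": age,
            "nichd_stage": names[stage_idx],
        }
    )


def generate_pair_table(
    universe: pd.DataFrame, pair: PairSpec, seed: int
) -> pd.DataFrame:
    """Attach independent Bernoulli drug/event indicators to the universe.

    Independence means the baseline per-stage odds ratio is 1: the pair
    carries no association until dynamics are injected.
    """
    rng = np.random.default_rng(seed)
    n = len(universe)
    table = universe.copy()
    table["drug"] = (rng.uniform(size=n) < pair.p_drug).astype(np.int8)
    table["event"] = (rng.uniform(size=n) < pair.p_event).astype(np.int8)
    table.attrs["pair_id"] = pair.pair_id
    return table


def generate_reports(config: GeneratorConfig) -> Iterator[tuple[PairSpec, pd.DataFrame]]:
    """Yield ``(pair, report table)`` for every catalog pair.

    All pairs share one universe (ids, ages, stages); indicator seeds are
    derived per pair from the master seed, so any single pair's table can
    be regenerated independently.
    """
    config.validate()
    universe = generate_universe(config.n_reports, config.stage_weights, seed_for(config.seed, "universe"))
    for pair in config.pair_catalog:
        yield pair, generate_pair_table(universe, pair, seed_for(config.seed, "pair", pair.pair_id))


def sample_control_pairs(
    catalog: Sequence[PairSpec], n_pos: int, n_neg: int, seed: int
) -> tuple[list[PairSpec], list[PairSpec]]:
    """Disjoint uniform random positive / negative control pair sets.

    The positive set is later augmented with reporting dynamics; the
    negative set is left untouched.
    """
    if n_pos + n_neg > len(catalog):
        raise ValueError(
            f"catalog of {len(catalog)} pairs cannot supply {n_pos} + {n_neg} controls"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(catalog), size=n_pos + n_neg, replace=False)
    pos = [catalog[i] for i in idx[:n_pos]]
    neg = [catalog[i] for i in idx[n_pos:]]
    return pos, neg


def reporting_summary(
    count_sets: dict[str, Sequence[float]],
    n_resamples: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare per-pair drug-event report counts between pair sets.

    For every ordered pair of sets, reports the two-sample Student t test
    and a resampling estimate of the mean difference (mean of differences
    of resampled set means, with a 95% percentile interval).  Used to check
    that augmentation leaves the amount of drug-event reporting unchanged
    relative to untouched controls.
    """
    names = list(count_sets)
    if len(names) < 2:
        raise ValueError("need at least two pair sets to compare")
    for name in names:
        if len(count_sets[name]) < 2:
            raise ValueError(f"set {name!r} has fewer than 2 pairs; variance undefined")
    rng = np.random.default_rng(seed)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            xa = np.asarray(count_sets[na], dtype=float)
            xb = np.asarray(count_sets[nb], dtype=float)
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            diffs = np.empty(n_resamples)
            for k in range(n_resamples):
                diffs[k] = (
                    rng.choice(xa, size=xa.size, replace=True).mean()
                    - rng.choice(xb, size=xb.size, replace=True).mean()
                )
            lo, hi = np.percentile(diffs, [2.5, 97.5])
            rows.append(
                {
                    "set_a": na,
                    "set_b": nb,
                    "mean_a": xa.mean(),
                    "mean_b": xb.mean(),
                    "t_stat": float(t),
                    "t_pvalue": float(p),
                    "resampled_mean_diff": float(diffs.mean()),
                    "diff_ci_lo": float(lo),
                    "diff_ci_hi": float(hi),
                }
            )
    return pd.DataFrame(rows)
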