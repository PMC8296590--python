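"""Simulated dynamic event-reporting profiles across development stages.

A *dynamics class* is the shape of the event-reporting probability among
drug-exposed reports as a function of NICHD stage: ``uniform`` (flat),
``increase``, ``decrease``, ``plateau`` (high in mid-childhood) and
``inverse_plateau`` (high at both extremes).  Shapes are built from
hyperbolic tangent curves rescaled to span [0, 1] over the seven stages.

The effect size is a fold change FC drawn from a shifted exponential
(1 + Exp(rate), rejection-truncated to [1, 10]).  A profile is normalized
so that the drug-report-weighted mean injected event rate equals
``base_event_rate * FC`` exactly: p(s) = r * (1 + (FC-1) * alpha * w(s))
with the scalar alpha solved under the constraint (and re-solved with
stages pinned at probability 1 when clamping binds).

Injection then replaces the event indicator of every drug-exposed report
with a Bernoulli draw at its stage's injected rate; non-drug reports — the
denominator of every disproportionality statistic — are untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .stages import STAGE_NAMES

__all__ = [
    "DYNAMICS_CLASSES",
    "DynamicsSpec",
    "InfeasibleEffectError",
    "sample_fold_change",
    "weight_curve",
    "injected_rate_profile",
    "inject_events",
]

DYNAMICS_CLASSES = ("uniform", "increase", "decrease", "plateau", "inverse_plateau")

#: Default curve geometry: steepness and centers on the 1..7 stage axis.
DEFAULT_STEEPNESS = 1.5
DEFAULT_CENTER = 4.0
DEFAULT_PLATEAU_CENTERS = (2.5, 5.5)

FC_RATE = 0.75
FC_MAX = 10.0


class InfeasibleEffectError(ValueError):
    """Requested mean injected rate exceeds 1 even with all stages saturated."""

    def __init__(self, fold_change: float, max_fold_change: float):
        self.max_fold_change = max_fold_change
        super().__init__(
            f"fold change {fold_change:g} infeasible: max achievable is "
            f"{max_fold_change:g} before stage probabilities exceed 1"
        )


def sample_fold_change(
    rate: float = FC_RATE, seed: int | np.random.Generator = 0, fc_max: float = FC_MAX
) -> float:
    """Draw one fold change: 1 + Exponential(rate), redrawn until <= ``fc_max``.

    Rejection (not clamping) keeps the distribution continuous on [1, fc_max].
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    while True:
        fc = 1.0 + rng.exponential(1.0 / rate)
        if fc <= fc_max:
            return float(fc)


def _rescale(w: np.ndarray) -> np.ndarray:
    lo, hi = w.min(), w.max()
    if hi - lo < 1e-12:
        return np.ones_like(w)
    return (w - lo) / (hi - lo)


def weight_curve(
    dynamics_class: str,
    steepness: float = DEFAULT_STEEPNESS,
    center: float = DEFAULT_CENTER,
    plateau_centers: tuple[float, float] = DEFAULT_PLATEAU_CENTERS,
) -> np.ndarray:
    """Per-stage injection weights w(s) in [0, 1] for s = 1..7.

    ``uniform`` is constant 1; the other classes are tanh sigmoids (or
    products of them) rescaled to span [0, 1] across the seven stages.
    """
    s = np.arange(1, 8, dtype=float)
    k = steepness
    if dynamics_class == "uniform":
        return np.ones(7)
    if dynamics_class == "increase":
        return _rescale((1.0 + np.tanh(k * (s - center))) / 2.0)
    if dynamics_class == "decrease":
        return _rescale((1.0 - np.tanh(k * (s - center))) / 2.0)
    c1, c2 = plateau_centers
    bump = ((1.0 + np.tanh(k * (s - c1))) / 2.0) * ((1.0 - np.tanh(k * (s - c2))) / 2.0)
    if dynamics_class == "plateau":
        return _rescale(bump)
    if dynamics_class == "inverse_plateau":
        return 1.0 - _rescale(bump)
    raise ValueError(f"unknown dynamics class {dynamics_class!r}; expected one of {DYNAMICS_CLASSES}")


def injected_rate_profile(
    dynamics_class: str,
    fold_change: float,
    base_event_rate: float,
    drug_reports_per_stage: Sequence[int],
    steepness: float = DEFAULT_STEEPNESS,
    center: float = DEFAULT_CENTER,
    plateau_centers: tuple[float, float] = DEFAULT_PLATEAU_CENTERS,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the per-stage injected event rates p(s) and return (p, w).

    Satisfies sum_s n(s) p(s) / sum_s n(s) == base_event_rate * fold_change
    exactly, where n(s) are the pair's drug-report counts per stage.  When
    the unconstrained solution pushes some p(s) past 1, those stages are
    pinned at 1 and the scale re-solved over the rest; a target mean above
    1 raises :class:`InfeasibleEffectError`.
    """
    r = float(base_event_rate)
    fc = float(fold_change)
    if not (0.0 < r < 1.0):
        raise ValueError("base_event_rate must be in (0, 1)")
    if fc < 1.0:
        raise ValueError("fold_change must be >= 1")
    n = np.asarray(drug_reports_per_stage, dtype=float)
    if n.shape != (7,) or (n < 0).any():
        raise ValueError("drug_reports_per_stage must be 7 nonnegative counts")
    if n.sum() <= 0:
        raise ValueError("pair has no drug reports; nothing to inject")
    w = weight_curve(dynamics_class, steepness, center, plateau_centers)

    target = r * fc
    if target > 1.0:
        raise InfeasibleEffectError(fc, 1.0 / r)
    if fc == 1.0:
        return np.full(7, r), w

    share = n / n.sum()
    pinned = np.zeros(7, dtype=bool)
    for _ in range(8):  # at most 7 stages can become pinned
        free = ~pinned
        wbar_free = float((share[free] * w[free]).sum())
        # mean over free stages must make up what pinned stages don't supply
        deficit = target - float(share[pinned].sum()) * 1.0 - float(share[free].sum()) * r
        if wbar_free <= 0:
            if abs(deficit) < 1e-12:
                alpha = 0.0
            else:
                raise InfeasibleEffectError(fc, _max_fc(r, w, share))
        else:
            alpha = deficit / (r * (fc - 1.0) * wbar_free)
        if alpha < 0:
            raise InfeasibleEffectError(fc, _max_fc(r, w, share))
        p = np.where(pinned, 1.0, r * (1.0 + (fc - 1.0) * alpha * w))
        over = (p > 1.0) & ~pinned
        if not over.any():
            # stages without drug reports are unconstrained; clamp for validity
            return np.minimum(p, 1.0), w
        pinned |= over
    raise InfeasibleEffectError(fc, _max_fc(r, w, share))  # pragma: no cover


def _max_fc(r: float, w: np.ndarray, share: np.ndarray) -> float:
    """Largest fold change reachable before the weighted mean rate hits 1."""
    return 1.0 / r


@dataclass
class DynamicsSpec:
    """A fully resolved injection profile for one drug-event pair.

    ``stage_weights`` is the class's shape w(s); ``injected_rate`` the
    solved p(s).  Serializable to JSON for provenance alongside each
    augmented dataset.
    """

    dynamics_class: str
    fold_change: float
    base_event_rate: float
    steepness: float = DEFAULT_STEEPNESS
    center: float = DEFAULT_CENTER
    plateau_centers: tuple[float, float] = DEFAULT_PLATEAU_CENTERS
    seed: int = 0
    stage_weights: tuple[float, ...] = field(default=None)  # type: ignore[assignment]
    injected_rate: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    @classmethod
    def solve(
        cls,
        dynamics_class: str,
        fold_change: float,
        base_event_rate: float,
        drug_reports_per_stage: Sequence[int],
        seed: int = 0,
        **curve_kwargs,
    ) -> "DynamicsSpec":
        p, w = injected_rate_profile(
            dynamics_class, fold_change, base_event_rate, drug_reports_per_stage, **curve_kwargs
        )
        return cls(
            dynamics_class=dynamics_class,
            fold_change=float(fold_change),
            base_event_rate=float(base_event_rate),
            seed=seed,
            stage_weights=tuple(w),
            injected_rate=tuple(p),
            **{k: curve_kwargs[k] for k in ("steepness", "center", "plateau_centers") if k in curve_kwargs},
        )

    def to_json(self) -> str:
        d = asdict(self)
        d["plateau_centers"] = list(self.plateau_centers)
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "DynamicsSpec":
        d = json.loads(text)
        d["plateau_centers"] = tuple(d["plateau_centers"])
        d["stage_weights"] = tuple(d["stage_weights"])
        d["injected_rate"] = tuple(d["injected_rate"])
        return cls(**d)


def inject_events(table: pd.DataFrame, spec: DynamicsSpec, seed: int | None = None) -> pd.DataFrame:
    """Redraw event indicators on drug-exposed rows at the injected rates.

    Reports with drug = 0 keep their original event indicator, so the
    baseline event-reporting rate in the comparator population is
    preserved.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    out = table.copy()
    p = dict(zip(STAGE_NAMES, spec.injected_rate))
    drug_mask = out["drug"].to_numpy() == 1
    stages = out.loc[drug_mask, "nichd_stage"].map(p).to_numpy(dtype=float)
    out.loc[drug_mask, "event"] = (rng.uniform(size=drug_mask.sum()) < stages).astype(np.int8)
    return out
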