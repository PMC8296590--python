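"""Penalized-spline logistic GAM over NICHD development stages.

The model is a logistic regression whose drug effect varies smoothly with
development stage:

    logit E(event) = beta0 + drug * f(stage),   f(stage s) = beta_s

with one smooth coefficient per stage (7 knots, one per ordered stage) and
a shared intercept — 8 parameters in total.  The smooth is regularized by
a quadratic *wiggliness* penalty on the stage coefficients,

    P(beta) = lambda * beta' (D'D + gamma I) beta,

where D is the second-order difference operator on the ordered stage axis
and the small ridge term ``gamma`` makes the penalty full-rank, so the
coefficients shrink all the way to zero as lambda grows (cubic-shrinkage
semantics for an ordered factor smooth).  The smoothing parameter is
chosen by minimizing a Laplace-approximate restricted marginal likelihood
(REML); generalized cross-validation is available as an alternative.

Because the linear predictor only depends on (stage, drug), fitting
aggregates the report table to at most 14 binomial rows, so the cost of a
fit is independent of the number of reports.

Per-stage risk scores are the fitted smooth coefficients on the log-odds
scale; they are always finite and (almost surely) nonzero, and their
standard errors come from the penalized-information covariance, which is
what lets a stage with no drug reports borrow strength from its
neighbours instead of producing an incomputable score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .stages import STAGE_NAMES

__all__ = ["StageGAM"]

N_STAGES = 7


def _difference_penalty(n: int, order: int, shrinkage: float) -> np.ndarray:
    d = np.eye(n)
    for _ in range(order):
        d = np.diff(d, axis=0)
    return d.T @ d + shrinkage * np.eye(n)


def _aggregate(stage_idx: np.ndarray, drug: np.ndarray, event: np.ndarray):
    """Collapse reports to binomial (pattern, trials, successes) rows."""
    pattern = stage_idx * 2 + drug  # 0..13
    trials = np.bincount(pattern, minlength=2 * N_STAGES).astype(float)
    successes = np.bincount(pattern, weights=event, minlength=2 * N_STAGES).astype(float)
    keep = trials > 0
    pat = np.nonzero(keep)[0]
    x = np.zeros((pat.size, 1 + N_STAGES))
    x[:, 0] = 1.0
    drug_rows = pat % 2 == 1
    x[drug_rows, 1 + pat[drug_rows] // 2] = 1.0
    return x, trials[keep], successes[keep]


class StageGAM(BaseEstimator):
    """Stage-by-drug penalized logistic GAM risk scorer.

    Parameters
    ----------
    lam : float or "REML" or "GCV", default "REML"
        Smoothing parameter, or the criterion used to choose it.
    penalty_order : int, default 2
        Order of the difference penalty on the stage coefficients.
    shrinkage : float, default 0.05
        Ridge weight added to the difference penalty so the smooth shrinks
        to zero (not to a free polynomial) in the large-lambda limit.
    max_iter : int, default 100
        Newton iteration cap per inner fit.
    tol : float, default 1e-9
        Convergence tolerance on the penalized-score norm.

    Attributes
    ----------
    intercept_ : float
        Baseline (non-drug) log odds of event reporting.
    coef_ : ndarray of shape (7,)
        Smooth drug-effect coefficient per NICHD stage (log odds ratio
        scale) — the per-stage risk scores.
    covariance_ : ndarray of shape (8, 8)
        Penalized-information (Bayesian posterior) covariance of
        (intercept, coef).
    lam_ : float
        Smoothing parameter used (chosen or given).
    n_iter_, converged_ : fit diagnostics.
    """

    def __init__(
        self,
        lam: float | str = "REML",
        penalty_order: int = 2,
        shrinkage: float = 0.05,
        max_iter: int = 100,
        tol: float = 1e-9,
    ):
        self.lam = lam
        self.penalty_order = penalty_order
        self.shrinkage = shrinkage
        self.max_iter = max_iter
        self.tol = tol

    # -- data marshalling ---------------------------------------------------

    @staticmethod
    def _design_from_X(X) -> tuple[np.ndarray, np.ndarray]:
        """Accept a DataFrame (nichd_stage, drug) or array (stage index, drug)."""
        if isinstance(X, pd.DataFrame):
            stage_idx = (
                pd.Categorical(X["nichd_stage"], categories=STAGE_NAMES).codes
            ).astype(np.int64)
            if (stage_idx < 0).any():
                raise ValueError("unknown nichd_stage value in X")
            drug = X["drug"].to_numpy(dtype=np.int64)
        else:
            arr = np.asarray(X)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("array X must have two columns: stage index (1..7), drug")
            stage_idx = arr[:, 0].astype(np.int64) - 1
            drug = arr[:, 1].astype(np.int64)
            if (stage_idx < 0).any() or (stage_idx >= N_STAGES).any():
                raise ValueError("stage index must be in 1..7")
        if not np.isin(drug, (0, 1)).all():
            raise ValueError("drug must be binary")
        return stage_idx, drug

    def fit(self, X, y):
        """Fit the GAM. ``X``: (stage, drug) per report; ``y``: binary event."""
        stage_idx, drug = self._design_from_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != stage_idx.shape[0]:
            raise ValueError("X and y length mismatch")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("event indicator must be binary")
        if drug.min() == drug.max():
            raise ValueError("need both drug=0 and drug=1 reports to fit")

        x, m, k = _aggregate(stage_idx, drug, y)
        s_pen = np.zeros((1 + N_STAGES, 1 + N_STAGES))
        s_smooth = _difference_penalty(N_STAGES, self.penalty_order, self.shrinkage)
        s_pen[1:, 1:] = s_smooth
        sign, logdet_s = np.linalg.slogdet(s_smooth)
        if sign <= 0:  # pragma: no cover - shrinkage > 0 guarantees PD
            raise ValueError("penalty matrix not positive definite")

        if isinstance(self.lam, str):
            crit = self.lam.upper()
            if crit not in ("REML", "GCV"):
                raise ValueError("lam must be a number, 'REML' or 'GCV'")

            def objective(log_lam: float) -> float:
                lam = np.exp(log_lam)
                beta, h, ll, ok = self._pirls(x, m, k, lam * s_pen)
                if crit == "REML":
                    _, logdet_h = np.linalg.slogdet(h)
                    pen = 0.5 * lam * beta @ s_pen @ beta
                    return -(ll - pen) + 0.5 * logdet_h - 0.5 * (
                        N_STAGES * log_lam + logdet_s
                    )
                # GCV on the binomial deviance with tau = trace of the hat matrix
                vp = np.linalg.inv(h)
                w = m * self._mu(x, beta) * (1 - self._mu(x, beta))
                tau = float(np.trace(vp @ (x.T * w) @ x))
                dev = self._deviance(x, m, k, beta)
                n_obs = m.sum()
                return n_obs * dev / (n_obs - tau) ** 2

            res = minimize_scalar(objective, bounds=(-10.0, 15.0), method="bounded")
            lam_opt = float(np.exp(res.x))
        else:
            lam_opt = float(self.lam)
            if lam_opt < 0:
                raise ValueError("lam must be nonnegative")

        beta, h, ll, ok = self._pirls(x, m, k, lam_opt * s_pen)
        if not ok:
            raise RuntimeError(
                f"GAM did not converge in {self.max_iter} Newton iterations "
                f"(lambda={lam_opt:g}); final penalized score norm above tol"
            )
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.covariance_ = np.linalg.inv(h)
        self.lam_ = lam_opt
        self.converged_ = ok
        self.n_params_ = beta.size
        self.loglik_ = float(ll)
        self._warn_if_stage_baseline_varies(stage_idx, drug, y)
        return self

    def fit_table(self, table: pd.DataFrame) -> "StageGAM":
        """Fit from a report table (columns nichd_stage, drug, event)."""
        return self.fit(table[["nichd_stage", "drug"]], table["event"].to_numpy())

    # -- inner penalized IRLS ----------------------------------------------

    @staticmethod
    def _mu(x: np.ndarray, beta: np.ndarray) -> np.ndarray:
        return expit(x @ beta)

    @staticmethod
    def _loglik(x, m, k, beta) -> float:
        eta = x @ beta
        # binomial log-likelihood up to the constant choose(m, k) term
        return float(k @ eta - m @ np.logaddexp(0.0, eta))

    def _deviance(self, x, m, k, beta) -> float:
        ll = self._loglik(x, m, k, beta)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_sat = np.clip(k / m, 1e-12, 1 - 1e-12)
        ll_sat = float(k @ np.log(p_sat) + (m - k) @ np.log1p(-p_sat))
        return 2.0 * (ll_sat - ll)

    def _pirls(self, x, m, k, pen: np.ndarray):
        """Newton iteration for the penalized binomial log-likelihood."""
        beta = np.zeros(x.shape[1])
        obj = self._loglik(x, m, k, beta) - 0.5 * beta @ pen @ beta
        ok = False
        it = 0
        h = None
        for it in range(1, self.max_iter + 1):
            mu = self._mu(x, beta)
            w = m * mu * (1 - mu)
            grad = x.T @ (k - m * mu) - pen @ beta
            h = (x.T * w) @ x + pen
            # tiny jitter keeps the unpenalized-corner case solvable
            step = np.linalg.solve(h + 1e-12 * np.eye(h.shape[0]), grad)
            t = 1.0
            for _ in range(30):
                cand = beta + t * step
                cand_obj = self._loglik(x, m, k, cand) - 0.5 * cand @ pen @ cand
                if cand_obj >= obj - 1e-14:
                    break
                t /= 2.0
            beta, obj = beta + t * step, cand_obj
            if np.linalg.norm(grad) < self.tol * (1.0 + abs(obj)):
                ok = True
                break
        mu = self._mu(x, beta)
        w = m * mu * (1 - mu)
        h = (x.T * w) @ x + pen + 1e-12 * np.eye(x.shape[1])
        return beta, h, self._loglik(x, m, k, beta), ok or it == 0

    def _warn_if_stage_baseline_varies(self, stage_idx, drug, y):
        """The model has no stage main effect; warn when baseline rates differ a lot.

        Only stages with enough expected events to estimate a rate reliably
        are compared, so small-stratum sampling zeros do not trigger it.
        """
        non_drug = drug == 0
        grp = pd.Series(y[non_drug]).groupby(stage_idx[non_drug])
        rates, sizes = grp.mean(), grp.size()
        pooled = y[non_drug].mean()
        informative = rates[sizes * max(pooled, 1e-12) >= 30]
        if len(informative) >= 2 and informative.max() > 0:
            lo = informative.min()
            if lo == 0 or informative.max() / lo > 5:
                warnings.warn(
                    "baseline event rates vary strongly across stages; the "
                    "stage-by-drug GAM has no stage main effect, so per-stage "
                    "scores are log odds ratios against the pooled baseline",
                    UserWarning,
                    stacklevel=3,
                )

    # -- prediction & scores -------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        stage_idx, drug = self._design_from_X(X)
        return self.intercept_ + drug * self.coef_[stage_idx]

    def predict_proba(self, X) -> np.ndarray:
        p1 = expit(self.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def stage_scores(self, z_lower: float = 1.2816) -> pd.DataFrame:
        """Per-stage risk scores: smooth coefficient, SE, and lower bound.

        ``lower`` = score − z_lower·SE is the one-sided lower confidence
        bound (default z gives the 90% bound).  All values are finite.
        """
        check_is_fitted(self, "coef_")
        se = np.sqrt(np.diag(self.covariance_)[1:])
        return pd.DataFrame(
            {
                "nichd_stage": STAGE_NAMES,
                "score": self.coef_,
                "se": se,
                "lower90": self.coef_ - z_lower * se,
            }
        )
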