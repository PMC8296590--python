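# Methods

This note documents the models, parameters, numerical choices and known
limitations of `pedsignal`.

## Report data model

A safety report is (report id, age in years, NICHD stage, drug ∈ {0,1},
event ∈ {0,1}). The report universe for a drug-event pair is *all*
pediatric reports (0 < age ≤ 21 years), not only drug-exposed ones: the
comparator arm of every statistic lives in the same table.

The seven NICHD stages partition (0, 21] with lower-exclusive /
upper-inclusive intervals, so age 21 is retained and age 0 excluded:

| stage | interval (years) |
|---|---|
| term_neonatal | (0, 27/365.25] |
| infancy | (27/365.25, 1] |
| toddler | (1, 2] |
| early_childhood | (2, 5] |
| middle_childhood | (5, 11] |
| early_adolescence | (11, 18] |
| late_adolescence | (18, 21] |

The day-level cutoffs at the young end follow NICHD pediatric
terminology; they are configuration, not constants, because regulatory
bodies draw these lines differently. Ages arriving in other units are
converted with a 365.25-day year (months = year/12, weeks = 7 days).

## Synthetic report generator

The generator emulates the *marginal* structure of a pediatric
spontaneous-report corpus at configurable scale. One shared universe of
`n_reports` reports is drawn: stage from a 7-vector of weights, age
uniform within the stage interval (all downstream statistics are
stage-level, so the within-stage age law is immaterial). Per pair, drug
and event indicators are independent Bernoullis with log-uniform
marginal rates across pairs (default ranges 0.005–0.05 for both),
mimicking the heavy skew of real reporting frequencies.

Default stage weights are (0.03, 0.12, 0.08, 0.12, 0.20, 0.25, 0.20) —
sparse neonatal reporting, heavier adolescence — a plausible pediatric
reporting profile chosen once; real per-stage report counts are not
published for the emulated corpus, so the weights are exposed as
configuration rather than asserted as fact.

Baseline independence of drug and event makes un-augmented pairs true
negative controls. Real spontaneous-report pairs can carry genuine
signal, co-reporting correlation, polypharmacy and duplicate case
versions; none of these are emulated, so passing tests demonstrate
method behaviour under clean marginals, not robustness to those
artifacts.

The desk-scale defaults — 50,000 reports, 50 positive and 500 negative
control pairs — mirror a full-scale design of 339,741 reports with
500/10,000 controls at roughly 1/7 scale. The resampling count in the
report-volume comparison defaults to 10,000 for desk runtime
(configurable; the full-scale analogue uses orders of magnitude more).

## Injected reporting dynamics

A dynamics class is a shape w(s) ∈ [0,1] over stages s = 1..7:

- `uniform`: w ≡ 1;
- `increase`: (1 + tanh(k(s − c)))/2, rescaled to span [0,1];
- `decrease`: its mirror;
- `plateau`: product of an ascending and a descending tanh sigmoid
  (centers c₁, c₂), rescaled — an interior bump;
- `inverse_plateau`: 1 − plateau.

Defaults k = 1.5, c = 4, (c₁, c₂) = (2.5, 5.5) reproduce the intended
qualitative shapes; only the class geometry (monotone / unimodal /
constant) and the effect-size constraint below are treated as normative,
and all curve parameters are configuration.

The effect size is a fold change FC ~ 1 + Exponential(rate 0.75),
re-drawn until ≤ 10 (rejection, not clamping, keeps the law continuous
on [1, 10]).

Per-stage injected event rates among drug reports are

p(s) = r · (1 + (FC − 1) · α · w(s)),

with r the pair's **non-drug** event reporting rate and the scalar α ≥ 0
solved so the drug-report-weighted mean of p(s) equals r · FC exactly.
If a stage's rate would exceed 1 it is pinned at 1 and α re-solved over
the remaining stages; a target mean above 1 raises an error reporting
the maximum feasible FC (1/r) instead of silently shrinking the effect.
The `uniform` class therefore yields p(s) = r·FC at every stage.

Injection *replaces* the event indicator of each drug-exposed report
with a Bernoulli(p(stage)) draw — it does not OR with the existing
indicator — so the realized rate equals the designed rate; non-drug rows
are untouched, preserving the comparator rate. The choice of the
non-drug rate (rather than the all-report rate) as the baseline r is a
documented convention; at realistic drug frequencies the two differ
negligibly.

## Detection methods

**PRR.** Per stage, PRR = (a/(a+c)) / (b/(b+d)). Quality classes: `nan`
when a+c = 0 (drug absent in the stratum), `infinite` when b = 0 with
a > 0, `zero` when a = 0, else `finite`. The lower-bound score type is
exp(ln PRR − z·σ) with σ² = 1/a − 1/(a+c) + 1/b − 1/(b+d); the
variance formula is the standard asymptotic one. z defaults to 1.2816
(one-sided 90% bound, "90mse"); 1.645 is a config switch for a
two-sided-90% reading.

**GAM.** Logistic model logit E(event) = β₀ + Drug·βₛ over the seven
ordered stage knots — 8 parameters. The smooth penalty is
λ·β'(D₂'D₂ + γI)β with D₂ the second-order difference operator and
γ = 0.05 a ridge weight that makes the penalty full-rank, so the smooth
shrinks all the way to zero (not to a free linear trend) as λ → ∞ —
the shrinkage semantics of a cubic-shrinkage basis for an ordered
factor. γ was fixed as part of the estimator design and validated by
the λ→0 oracle (agreement with unpenalized logistic regression) and
large-n parameter recovery.

λ is chosen by minimizing a Laplace-approximate restricted marginal
likelihood: −ℓ(β̂) + ½λβ̂'Sβ̂ + ½log|X'WX + λS̃| − ½(7·log λ + log|S|),
optimized over log λ ∈ [−10, 15] (bounded scalar minimization); GCV on
the binomial deviance is available as an alternative, and λ is always
reported (`lam_`) so fits are auditable. The inner problem is Newton
iteration with step halving on at most 14 aggregated binomial rows
(stage × drug patterns), making fit cost independent of the number of
reports. Per-stage SEs come from the penalized-information (Bayesian
posterior) covariance (X'WX + λS̃)⁻¹; this is what keeps scores finite
and interpolated at stages with no drug reports.

The model deliberately has **no stage main effect** — exactly the
scored formula — so per-stage scores are log odds ratios against the
pooled non-drug baseline. The generator's baseline event rate is
stage-constant, matching this assumption; on data whose baseline varies
strongly across stages a diagnostic warning is raised.

The "90mse" GAM score is βₛ − z·SE(βₛ) from the analytic covariance; a
bootstrap-replicate alternative would be admissible but is not
implemented.

## Power-calibrated reference standards

Each positive pair is augmented under all five classes (one fresh FC per
(pair, class); seeds derived by stable hashing). Scores from
(pair, stage, class) triples are only trusted at the class's
*high-reporting* stages — where its weight curve is near peak; default
masks: increase → {early_adolescence, late_adolescence}, decrease →
{term_neonatal, infancy}, plateau → {early_childhood, middle_childhood},
inverse_plateau → {term_neonatal, late_adolescence}, uniform → all.
These masks follow the curve geometry (config-overridable); triples at
low-reporting stages are dropped as carrying no injected signal.

Per (method, score type, class), power over a decile grid of (minimum
per-stage drug reports n, minimum FC) is the fraction of qualifying
triples scoring strictly above the method's null (PRR 1, GAM 0; NaN
never detects). The frontier is the grid point with power ≥ t = 0.80
maximizing the number of qualifying triples (ties toward smaller n,
then smaller FC — "largest fair positive set"). The class's reference
standard takes the union of the per-method qualifying triples as
positives (per-method flags retained for audit) and every
(negative pair, stage) double as negatives — identical across the four
class standards; the uniform class defines none.

## Evaluation

AUROC is the rank statistic (ties ½). NaN-quality scores are excluded
from ranking and threshold calls with counts reported; zeros are kept;
+∞ ranks above all finite scores. Sensitivity/PPV/NPV use strict ">"
for positive calls at the null threshold. Confidence intervals are
percentile bootstrap over 100 resamples, positives and negatives
resampled independently (resampling is over score instances/pairs, not
reports). Class-vs-uniform score contrasts use 20 pair-resamples with a
95% percentile interval — deliberately few, so those intervals are
noisy by construction.

The removal sensitivity analysis deletes a uniform random fraction
(0, 0.1, …, 1) of drug-exposed rows at one stage (without replacement,
reseeded per stage/fraction/pair), rescores everything, and evaluates at
that stage only. Deleting rows lowers drug reporting while leaving the
comparator event rate intact; at fraction 1 the PRR becomes incomputable
(`nan`) at the stage while GAM scores remain finite.

Real-world validation consumes a curated reference CSV (drug ATC id,
event MedDRA id, Control flag; positives are 'C' rows) and reduces the
7 stage scores of each pair to one prediction by max over stages (mean
is the config alternative; the reduction is a convention, chosen to
match an "in at least one stage" reading of significance). It reports
AUROC/sensitivity per method and score type, a per-pair quality and
significance tally, and a two-proportion χ² test between methods. The
repository ships no real reference data; tests exercise the protocol on
synthetic stand-ins.

## Problem sizes and determinism

Default test-suite runs use the desk-scale profile above; the GAM
parameter-recovery check uses a single 200,000-report pair; effect-size
contracts are verified at 50,000 reports; these sizes were chosen as the
smallest at which the binomial/SE-based assertions are statistically
meaningful. Every stochastic step seeds from the master seed via
SHA-256 hashing of a token path (`util.seed_for`), so end-to-end runs
are bit-reproducible and intermediate artifacts (e.g. the tables the
removal analysis rescores) are regenerated rather than stored.

## Known limitations

- Stage-level resolution only: no calendar-time dynamics and no
  continuous-age smooths (a natural extension of the GAM).
- The GAM omits a stage main effect by design; on corpora with strongly
  stage-varying baseline rates its scores conflate baseline and drug
  effects (diagnostic warning, not a correction).
- Synthetic negatives are exactly null; real negative controls are not.
- Bayesian disproportionality baselines (BCPNN, EBGM) are out of scope.
- The high-reporting stage masks are geometric defaults, not estimates.
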