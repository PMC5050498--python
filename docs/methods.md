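# Methods

## Signal model

The raw observable is a per-subject sequence of key events
(label, press time, release time) from natural typing.  The analysis
uses only the hold time HT = release − press of keys expected to have
reflex-length holds: alphanumerics, printable symbols and the space bar.
Modifier, navigation and editing keys (shift/ctrl/alt/meta, arrows,
function keys, enter, backspace, delete) are held deliberately and are
excluded; backspace exclusion is a documented convention and can be
overridden by supplying an explicit `key_class` column.  Timestamps are
session-relative with t = 0 at the first *retained* key press, which
fixes the window grid.

The hold-time series is cut into non-overlapping half-open windows
[i·N<sup>w</sup>, (i+1)·N<sup>w</sup>) with N<sup>w</sup> = 90 s,
assignment by press time only (a hold may straddle a boundary; a press
at exactly i·N<sup>w</sup> belongs to window i).  Windows with fewer
than N<sup>w</sup>/3 = 30 samples are discarded: bursty typing leaves
near-empty windows whose statistics are meaningless.

## Features

Each retained window yields a 7-vector in fixed order
(v_out, v_skew, h1, h2, h3, h4, v_de):

* **v_out** — fraction of holds more than 1.5 IQR below q1 or above q3.
  Quartiles use linear interpolation between order statistics (the
  "type 7" rule); the estimator choice is a convention and every test
  oracle uses the same rule.
* **v_skew** — (q2 − q1)/(q3 − q1).  When q3 == q1 (at least half the
  window identical) the symmetric value 0.5 is returned by convention.
* **h1..h4** — counts in half-open bins [0, .125), [.125, .25),
  [.25, .375), [.375, .5) s divided by the *total* window count, so
  holds ≥ 0.5 s appear as missing mass (bin sum < 1) rather than being
  folded into the last bin.  Long holds are likewise retained when
  computing v_out/v_skew.
* **v_de** — for consecutive keystrokes (press-time order, never across
  a window boundary) the rollover overlap release(first) − press(second)
  clamped at 0, averaged over the window's pairs.  The mean (rather
  than a sum or count) keeps units of seconds and is invariant to the
  number of pairs.  A one-keystroke window returns 0.

All features are bounded or small-valued, which is why no feature
standardization is applied before regression by default (a flag enables
z-scoring fit on training data only).

## Ensemble regression

Each ensemble member is a linear ε-SVR minimizing
½‖w‖² + C·Σ(ξ + ξ*) under the ε-insensitive constraints, solved by
libsvm (scikit-learn `SVR(kernel="linear")`, tolerance 1e-6).  Defaults
C = 0.094, ε = 0.052 are the product of a leave-one-subject-out AUC
grid search on an external tuning cohort; `grid_search_hyperparams`
re-implements that selection (default grids C ∈ 2⁻¹⁰…2⁴, 15 points;
ε ∈ 0.01…0.10 step 0.01; ties break toward smaller C then smaller ε).

Targets are UPDRS-III motor totals divided by the fixed scale maximum
108.  A fixed divisor keeps scores comparable across cohorts; any
per-cohort min–max normalization would leak evaluation statistics into
training.

Bagging draws N<sup>m</sup> = 200 bootstrap resamples with replacement
at the *window-vector* level, size equal to the training set (a
subject-level bootstrap is available as an option for leakage probing).
A window's score is the median of the member predictions (mean of the
two central order statistics for even N<sup>m</sup>); the subject nQi
is the arithmetic mean of the subject's window scores.  The bootstrap
RNG is seeded (default 20161005) and fits are bit-reproducible.

Degenerate fits: when the entire target range fits inside one ε-tube
(ptp(y) ≤ 2ε, including constant targets) the primal optimum is a flat
function with zero loss and any intercept in [max(y)−ε, min(y)+ε].
`train_svr` returns the canonical midrange intercept with w = 0 exactly,
so degenerate fits are deterministic instead of an arbitrary point of
the flat optimum.  More generally the primal can have a flat optimal
*interval* in b at small C; correctness is therefore judged by primal
objective value and by w (unique by strict convexity), with b required
only to lie in the optimal interval.

## Evaluation stack

* **AUC** is the normalized Mann–Whitney U (ties ½), positive class PD,
  higher score = more PD-like.  Variance via DeLong's
  structural-components estimator; 95% CI as auc ± 1.96·se, computed on
  the logit scale when AUC > 0.95 so the interval stays in [0, 1].
* **DeLong test** for two correlated curves uses the paired covariance
  of the placement values.  Identical curves return (z = 0, p = 1); a
  nonzero difference with numerically zero variance returns z = ±∞,
  p = 0.
* **Cutoffs** maximize J = se − m·(1 − sp) with
  m = (cost_FP/cost_FN)·(1 − prev)/prev and prevalence estimated from
  the evaluated sample; candidate thresholds are midpoints of adjacent
  unique scores plus ±∞, rule score ≥ t → PD, ties toward higher
  specificity.  Reported sens/spec/acc round half-up to 2 decimals.
  The exact cost/prevalence weighting of the generalized index is a
  documented choice among published variants.
* **Cross-dataset validation** trains on cohort A to score cohort B and
  vice versa (disjoint subjects enforced), then pools the held-out
  scores without retraining.  A fold whose scores are constant up to
  sub-ulp accumulation jitter is flagged and reported as AUC 0.5 by
  ties — that jitter carries no ranking information.
* **Adjusted logistic** fits group ~ nQi + age + sex + education +
  typing speed by maximum likelihood (statsmodels), reporting Wald
  z/p per term.  Perfect separation is detected and flagged; p-values
  are then withheld.  Zero-variance covariate columns are dropped as
  unidentifiable, which also makes the all-zero-covariate fit reduce
  exactly to the univariate fit.

## Synthetic cohorts

The generator plants precisely the structure the method is designed to
detect, with defaults chosen once as the study conditions:

* sessions ~ Normal(14, 2.9) minutes clipped to [8, 20] (≈ ±2 sd; the
  lower clip guarantees every subject enough 90-s windows for a stable
  score); typing in bursts (geometric, mean ~15 keys) separated by
  exponential pauses (mean 2.5 s) with occasional long pauses
  (prob 0.02/burst, 40–120 s) that exercise the sparsity filter;
* hold times lognormal, subject-specific median around 100 ms
  (log-location jitter sd 0.15), shape σ = 0.35 — >95% of control holds
  fall in [0, 0.5) s;
* a two-state Markov regime per subject (enter 0.02, exit 0.05 per
  keystroke) whose inflated state multiplies σ by
  1 + severity·severity_effect and injects heavy-tail holds
  (lognormal around 0.35 s) with probability
  0.3·min(1, severity·severity_effect) — transient variance, not a
  mean shift, is the discriminating signal;
* latent severity ∈ [0, 1] drives both typing and a synthetic
  UPDRS-III = round(108·severity·0.38 + N(0, 1.5)) clipped to [0, 108];
  PD severities ~ U(0.25, 0.75) and controls ~ U(0, 0.09) put group
  means near 20 and 2 on the UPDRS-III scale;
* covariates (age, sex, education, typing speed) are drawn identically
  in both groups, so adjusted analyses see the no-confounding case;
  5% of keys are ineligible (shift/backspace/enter) with deliberately
  long holds, exercising the eligibility filter.

With `severity_effect = 0` the typing process is exchangeable between
groups (labels and UPDRS still differ), giving the matched null
condition.

What the generator does **not** emulate: key-identity sequences and
language, error correction behaviour, medication cycles, fatigue or
practice drift, device/OS timing artefacts, or comorbid conditions.
Passing end-to-end tests therefore shows the pipeline recovers a
planted heteroscedastic hold-time signal at realistic sample sizes —
not that the score generalises to clinical populations.

## Problem sizes and statistical reading of the checks

End-to-end checks use two cohorts of 40 subjects (20 PD / 20 control)
each, ~8 windows per subject, ensembles of 200 members, five seeds per
condition.  At that size a single cross-dataset AUC under the null has
Monte-Carlo sd ≈ 0.07, so chance-level behaviour is asserted on the AUC
averaged over the five seeds (sd ≈ 0.03), while the strong-effect bound
(AUC ≥ 0.85 at severity_effect = 2) holds per seed with margin.  DeLong
variances are validated against a 2000-replicate stratified subject
bootstrap; the adjusted-logistic score term is calibrated on 500 null
cohorts of 85 subjects (observed type-I rate ≈ 0.05).

## Known limitations

* The eligibility classifier is keyword-based; unusual key names
  default to ineligible ("other"), which is conservative for the HT
  signal but may drop legitimate symbol keys from exotic layouts.
* Quartile-estimator and histogram-normalization conventions affect
  feature values slightly; alternatives are not configurable beyond
  the documented flags.
* The generalized Youden index is implemented in one specific
  cost/prevalence weighting; other published variants select slightly
  different thresholds on the same data.
* Subject scores assume windows are exchangeable within a session; no
  time-of-session or fatigue modelling is attempted.
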