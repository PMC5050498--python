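"""ROC analysis, DeLong inference, cost-weighted cutoffs, cross-dataset
validation and covariate-adjusted significance testing for nQi scores.

Scores are oriented so that larger means more PD-like; the positive
class is ``"PD"``.  The AUC is the probability that a randomly chosen
PD subject scores higher than a randomly chosen control (ties counted
half), i.e. the normalized Mann–Whitney U statistic.  Uncertainty uses
DeLong's structural-components estimator, which also yields the paired
test comparing two correlated ROC curves on the same subjects.

Cutoff selection maximizes a generalized Youden index

    J = sensitivity − m · (1 − specificity),
    m = (cost_FP / cost_FN) · (1 − prevalence) / prevalence

with prevalence estimated from the evaluated sample, so unequal
misclassification costs shift the operating point along the ROC curve.

The cross-dataset harness mirrors a conservative two-cohort design:
train on cohort A to score cohort B and vice versa, then pool the two
held-out score sets without further training.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "CutoffResult",
    "RocResult",
    "adjusted_logistic",
    "confusion_stats",
    "cross_dataset_validate",
    "delong_test",
    "per_window_auc",
    "roc_auc",
    "youden_cutoff",
]

POSITIVE_LABEL = "PD"


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "biu":
        return labels.astype(int)
    return (labels == POSITIVE_LABEL).astype(int)


@dataclass
class RocResult:
    """ROC curve with DeLong-based AUC uncertainty."""

    auc: float
    se: float
    ci95: tuple[float, float]
    curve: pd.DataFrame  # columns fpr, tpr, threshold
    n_pos: int
    n_neg: int


@dataclass
class CutoffResult:
    """Operating point chosen by the generalized Youden index."""

    cost_fn: float
    cost_fp: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def rounded(self) -> tuple[float, float, float]:
        """(sensitivity, specificity, accuracy) rounded half-up to 2 dp."""
        return confusion_stats(self.tp, self.fn, self.tn, self.fp)[1]


def _structural_components(scores: np.ndarray, y: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    # pairwise comparison with ties counted 1/2
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01


def roc_auc(scores, labels) -> RocResult:
    """AUC with DeLong variance and 95% CI, plus the full ROC curve.

    The CI is ``auc ± 1.96·se`` clipped to [0, 1]; for AUC > 0.95 it is
    computed on the logit scale and back-transformed so the interval
    stays inside the unit square.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if len(set(y)) < 2:
        raise ValueError("roc_auc requires both classes")
    v10, v01 = _structural_components(scores, y)
    m, n = v10.size, v01.size
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    if 0.95 < auc < 1.0 and se > 0:
        logit = np.log(auc / (1 - auc))
        lse = se / (auc * (1 - auc))
        lo, hi = logit - z * lse, logit + z * lse
        ci = (float(1 / (1 + np.exp(-lo))), float(1 / (1 + np.exp(-hi))))
    else:
        ci = (
            float(np.clip(auc - z * se, 0.0, 1.0)),
            float(np.clip(auc + z * se, 0.0, 1.0)),
        )
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return RocResult(auc=auc, se=se, ci95=ci, curve=curve, n_pos=m, n_neg=n)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided DeLong test for two correlated ROC curves.

    Both score sets must be measured on the same subjects in the same
    order.  Returns (z, p) for H0: AUC_a == AUC_b.  Identical curves
    give (0, 1); a nonzero AUC difference with (numerically) zero
    variance gives infinite z and p = 0.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score sets must have equal length")
    y = _as_binary(labels)
    va10, va01 = _structural_components(scores_a, y)
    vb10, vb01 = _structural_components(scores_b, y)
    m, n = va10.size, va01.size
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())

    def _cov(u, v):
        return float(np.cov(u, v, ddof=1)[0, 1]) if u.size > 1 else 0.0

    var_diff = (
        (np.var(va10, ddof=1) + np.var(vb10, ddof=1) - 2 * _cov(va10, vb10)) / m
        + (np.var(va01, ddof=1) + np.var(vb01, ddof=1) - 2 * _cov(va01, vb01)) / n
    )
    diff = auc_a - auc_b
    if not np.isfinite(var_diff):
        raise ValueError("degenerate DeLong variance (non-finite)")
    if var_diff <= 1e-15:
        if abs(diff) <= 1e-12:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    z = diff / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single AUC (exposed for calibration checks)."""
    v10, v01 = _structural_components(np.asarray(scores, float), _as_binary(labels))
    return float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)


def confusion_stats(tp: int, fn: int, tn: int, fp: int):
    """Sensitivity, specificity, accuracy from confusion counts.

    Returns ``(exact, rounded)`` where ``rounded`` applies half-up
    rounding to two decimals for presentation.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("undefined metric: empty class")
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / (tp + fn + tn + fp)

    def _round2(x: float) -> float:
        return float(Decimal(repr(x)).quantize(Decimal("0.01"), ROUND_HALF_UP))

    return (se, sp, acc), (_round2(se), _round2(sp), _round2(acc))


def youden_cutoff(scores, labels, cost_fn_fp: tuple[float, float] = (1.0, 1.0)) -> CutoffResult:
    """Pick the threshold maximizing the generalized Youden index.

    ``cost_fn_fp`` is (per-FN cost, per-FP cost); a subject is called PD
    when score ≥ threshold.  Candidate thresholds are the midpoints
    between adjacent sorted unique scores plus ±∞; ties in J break
    toward higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if len(set(y)) < 2:
        raise ValueError("youden_cutoff requires both classes")
    cost_fn, cost_fp = cost_fn_fp
    if cost_fn <= 0 or cost_fp <= 0:
        raise ValueError("misclassification costs must be positive")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    prev = n_pos / y.size
    m = (cost_fp / cost_fn) * ((1 - prev) / prev)

    uniq = np.unique(scores)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))

    best = None
    for thr in candidates:
        pred = scores >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = n_pos - tp
        tn = n_neg - fp
        se = tp / n_pos
        sp = tn / n_neg
        j = se - m * (1 - sp)
        key = (j, sp)
        if best is None or key > best[0]:
            best = (key, thr, se, sp, tp, fn, tn, fp)
    (_, _), thr, se, sp, tp, fn, tn, fp = best
    return CutoffResult(
        cost_fn=cost_fn, cost_fp=cost_fp, threshold=float(thr),
        sensitivity=se, specificity=sp,
        accuracy=(tp + tn) / y.size, tp=tp, fn=fn, tn=tn, fp=fp,
    )


def cross_dataset_validate(
    features_a: pd.DataFrame,
    metadata_a: pd.DataFrame,
    features_b: pd.DataFrame,
    metadata_b: pd.DataFrame,
    **model_kwargs,
) -> dict:
    """Two-fold cross-cohort validation.

    Trains on cohort A to score cohort B and vice versa, then pools the
    held-out scores without further training.  Returns a dict with the
    per-fold and combined :class:`RocResult`, the pooled per-subject
    score table, and window-level score tables for per-window analysis.
    """
    from .model import NQIModel

    subj_a = set(metadata_a["subject_id"].astype(str))
    subj_b = set(metadata_b["subject_id"].astype(str))
    overlap = subj_a & subj_b
    if overlap:
        raise ValueError(f"cohorts share subjects: {sorted(overlap)[:5]}")

    def _fold(train_feat, train_meta, test_feat, test_meta):
        res = NQIModel(train_feat, train_meta, **model_kwargs).fit()
        subject_scores = res.score_subjects(test_feat)
        meta = test_meta.set_index("subject_id")["group"]
        subject_scores["group"] = subject_scores["subject_id"].map(meta).to_numpy()
        window_scores = test_feat.loc[:, ["subject_id", "window_index"]].copy()
        window_scores["score"] = res.predict_windows(test_feat)
        window_scores["group"] = window_scores["subject_id"].map(meta).to_numpy()
        return subject_scores, window_scores

    scores_b, win_b = _fold(features_a, metadata_a, features_b, metadata_b)
    scores_a, win_a = _fold(features_b, metadata_b, features_a, metadata_a)

    combined = pd.concat([scores_a, scores_b], ignore_index=True)
    windows = pd.concat([win_a, win_b], ignore_index=True)

    def _roc(df, col):
        vals = df[col].to_numpy(dtype=float)
        # a degenerate (flat-fit) model yields constant scores up to
        # sub-ulp accumulation jitter; that jitter carries no ranking
        # information, so collapse it and report AUC 0.5 by ties
        if np.ptp(vals) <= 1e-9 * max(1.0, float(np.abs(vals).max())):
            import warnings

            warnings.warn("zero-variance scores in fold; AUC is 0.5 by ties")
            vals = np.full_like(vals, vals.mean())
        return roc_auc(vals, df["group"].to_numpy())

    return {
        "roc_a": _roc(scores_a, "nqi"),
        "roc_b": _roc(scores_b, "nqi"),
        "roc_combined": _roc(combined, "nqi"),
        "subject_scores": combined,
        "window_scores": windows,
    }


def per_window_auc(window_scores: pd.DataFrame) -> RocResult:
    """ROC over window-level scores, labels inherited from the subject.

    Expects the ``window_scores`` table emitted by
    :func:`cross_dataset_validate` (columns ``score`` and ``group``).
    """
    return roc_auc(
        window_scores["score"].to_numpy(dtype=float),
        window_scores["group"].to_numpy(),
    )


def adjusted_logistic(
    scores,
    labels,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Logistic regression of group on score, adjusted for covariates.

    ``covariates`` may hold age, sex, education_years and typing_speed;
    sex is encoded M = 1, F = 0.  Zero-variance covariate columns are
    dropped (they are unidentifiable).  Returns a coefficient table
    (estimate, se, z, p per term) with ``attrs["separation"]`` set when
    the fit is perfectly separated, in which case Wald p-values are
    meaningless and set to NaN.
    """
    import statsmodels.api as sm

    y = _as_binary(labels)
    X = pd.DataFrame({"nqi": np.asarray(scores, dtype=float)})
    if covariates is not None:
        cov = covariates.copy()
        if "sex" in cov.columns and cov["sex"].dtype == object:
            cov["sex"] = (cov["sex"] == "M").astype(float)
        for col in cov.columns:
            vals = cov[col].astype(float)
            if np.ptp(vals.to_numpy()) == 0:
                continue  # constant column: unidentifiable, drop
            X[col] = vals.to_numpy()
    X = sm.add_constant(X, has_constant="add")

    separation = False
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            # fitted probabilities pinned at 0/1 indicate separation
            p_hat = fit.predict(X)
            if np.all((p_hat > 0.999) == (y == 1)) and np.all(
                (p_hat < 0.001) == (y == 0)
            ):
                separation = True
        except Exception:
            separation = True
            fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-8, maxiter=500)

    table = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse if not separation else np.nan,
            "z": fit.params / fit.bse if not separation else np.nan,
            "p": fit.pvalues if not separation else np.nan,
        }
    )
    table.attrs["separation"] = separation
    return table
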