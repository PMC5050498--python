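"""Bagged linear ε-SVR ensemble mapping window features to an nQi score.

The motor index is produced by an ensemble F = {f_1 … f_N^m} of linear
ε-support-vector-regression models.  Each f_m(x) = w_m·x + b_m is
trained on a bootstrap resample (drawn with replacement at the
window-vector level, size equal to the training set) of the pairs
(x_i, y_i), where x_i is a window feature vector and y_i the subject's
UPDRS-III motor score normalized to [0, 1] by the fixed 108-point scale
maximum.  Every member uses the same ε-insensitive primal

    min_{w,b}  ½‖w‖² + C Σ_i (ξ_i + ξ*_i)
    s.t.       |w·x_i + b − y_i| ≤ ε + ξ_i (ξ*, slack ≥ 0)

with C and ε fixed (defaults C = 0.094, ε = 0.052, the optimum found by
leave-one-subject-out grid search on an external tuning cohort).  A
window's nQi is the median of the N^m member predictions (mean of the
two central order statistics for even N^m); a subject's nQi is the
arithmetic mean of their window scores.  Bagging plus the median
stabilises the score against resampling noise and outlying members.

Organisation follows the familiar model/results split:
``NQIModel(features, metadata).fit()`` returns :class:`NQIResults`,
which carries the fitted ensemble, predicts window and subject scores,
serialises to a versioned text format, and prints a ``summary()``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .features import FEATURE_COLUMNS

__all__ = [
    "UPDRS3_MAX",
    "NQIModel",
    "NQIResults",
    "grid_search_hyperparams",
    "normalize_updrs",
    "train_svr",
]

UPDRS3_MAX = 108  # UPDRS motor-section maximum
DEFAULT_C = 0.094
DEFAULT_EPSILON = 0.052
DEFAULT_N_MODELS = 200
DEFAULT_SEED = 20161005
SOLVER_TOL = 1e-6

_SERIAL_VERSION = 1


def normalize_updrs(updrs3: float) -> float:
    """Map a UPDRS-III total onto [0, 1] by the fixed 108-point maximum.

    A fixed scale keeps targets comparable across cohorts; per-cohort
    min–max scaling would leak test-set statistics into training.
    """
    if not 0 <= updrs3 <= UPDRS3_MAX:
        raise ValueError(f"UPDRS-III {updrs3!r} outside the 0-{UPDRS3_MAX} scale")
    return updrs3 / UPDRS3_MAX


def train_svr(X, y, C: float = DEFAULT_C, epsilon: float = DEFAULT_EPSILON,
              tol: float = SOLVER_TOL) -> tuple[np.ndarray, float]:
    """Fit one linear ε-SVR and return its primal coefficients (w, b).

    Delegates to the libsvm solver (sklearn ``SVR(kernel="linear")``).
    When the whole target range fits inside the ε-tube (ptp(y) ≤ 2ε,
    which covers zero-variance targets) the optimum is degenerate: any
    flat function through the tube has zero loss.  That case returns
    the canonical minimal-norm midrange solution (w = 0,
    b = (min y + max y)/2) exactly, so degenerate fits are
    deterministic rather than an arbitrary point of the flat optimum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite features or targets")
    if C <= 0 or epsilon <= 0:
        raise ValueError("C and epsilon must be positive")
    if np.ptp(y) <= 2 * epsilon:
        return np.zeros(X.shape[1]), float((y.min() + y.max()) / 2)
    svr = SVR(kernel="linear", C=C, epsilon=epsilon, tol=tol)
    svr.fit(X, y)
    return svr.coef_.ravel().copy(), float(svr.intercept_[0])


def _predict_members(weights: np.ndarray, biases: np.ndarray, X: np.ndarray) -> np.ndarray:
    return X @ weights.T + biases  # (n_samples, n_models)


@dataclass
class NQIModel:
    """Specification of an nQi ensemble fit.

    Parameters
    ----------
    features
        Window feature table (``subject_id`` plus the 7 feature
        columns), e.g. from :func:`nqi.features.featurize_series`.
    metadata
        Per-subject table with ``subject_id`` and ``updrs3``; every
        subject in ``features`` must appear.
    C, epsilon, n_models, seed
        Ensemble hyperparameters.  The bootstrap RNG is seeded so a fit
        is bit-reproducible.
    bootstrap
        Disable to train every member on the full set (degenerates the
        ensemble to N^m copies of one model; useful for testing).
    subject_bootstrap
        Resample whole subjects instead of individual windows (off by
        default; useful for probing leakage sensitivity).
    standardize
        Z-score features using training-set statistics before fitting
        (off by default: the features are already bounded fractions,
        histogram masses and small second-valued overlaps).
    """

    features: pd.DataFrame
    metadata: pd.DataFrame
    C: float = DEFAULT_C
    epsilon: float = DEFAULT_EPSILON
    n_models: int = DEFAULT_N_MODELS
    seed: int = DEFAULT_SEED
    bootstrap: bool = True
    subject_bootstrap: bool = False
    standardize: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.features.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        meta = self.metadata.set_index("subject_id")["updrs3"]
        subjects = self.features["subject_id"].astype(str)
        unknown = set(subjects) - set(meta.index.astype(str))
        if unknown:
            raise ValueError(f"subjects without metadata: {sorted(unknown)[:5]}")
        self._X = self.features.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        self._y = np.array(
            [normalize_updrs(meta[s]) for s in subjects], dtype=float
        )
        self._subjects = subjects.to_numpy()

    def fit(self) -> "NQIResults":
        """Train the bagged ensemble; deterministic given the seed."""
        if self._X.shape[0] == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.seed)
        X, y = self._X, self._y

        mu = sigma = None
        if self.standardize:
            mu = X.mean(axis=0)
            sigma = X.std(axis=0)
            sigma[sigma == 0] = 1.0
            X = (X - mu) / sigma

        n = X.shape[0]
        weights = np.empty((self.n_models, X.shape[1]))
        biases = np.empty(self.n_models)
        subject_ids = pd.unique(self._subjects)
        for m in range(self.n_models):
            if not self.bootstrap:
                idx = np.arange(n)
            elif self.subject_bootstrap:
                picked = rng.choice(subject_ids, size=subject_ids.size, replace=True)
                idx = np.concatenate(
                    [np.flatnonzero(self._subjects == s) for s in picked]
                )
            else:
                idx = rng.integers(0, n, size=n)
            weights[m], biases[m] = train_svr(
                X[idx], y[idx], C=self.C, epsilon=self.epsilon
            )
        fingerprint = hashlib.sha256(
            np.ascontiguousarray(X).tobytes() + y.tobytes()
        ).hexdigest()[:16]
        return NQIResults(
            model=self,
            weights=weights,
            biases=biases,
            feature_mean=mu,
            feature_scale=sigma,
            training_fingerprint=fingerprint,
        )


@dataclass
class NQIResults:
    """A fitted nQi ensemble: N^m (w, b) pairs plus provenance."""

    model: NQIModel | None
    weights: np.ndarray          # (n_models, 7)
    biases: np.ndarray           # (n_models,)
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None
    training_fingerprint: str = ""
    C: float = field(default=None)        # type: ignore[assignment]
    epsilon: float = field(default=None)  # type: ignore[assignment]
    seed: int = field(default=None)       # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        if self.C is None:
            self.C = self.model.C if self.model else DEFAULT_C
        if self.epsilon is None:
            self.epsilon = self.model.epsilon if self.model else DEFAULT_EPSILON
        if self.seed is None:
            self.seed = self.model.seed if self.model else DEFAULT_SEED

    @property
    def n_models(self) -> int:
        return self.weights.shape[0]

    # -- prediction ----------------------------------------------------

    def _design(self, features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            X = features.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(features, dtype=float))
        if self.feature_mean is not None:
            X = (X - self.feature_mean) / self.feature_scale
        return X

    def predict_window(self, x) -> float:
        """Partial nQi of one window: median over ensemble members."""
        return float(self.predict_windows(np.atleast_2d(x))[0])

    def predict_windows(self, features) -> np.ndarray:
        """Median member prediction for each row of a feature table."""
        X = self._design(features)
        return np.median(_predict_members(self.weights, self.biases, X), axis=1)

    def score_subjects(self, features: pd.DataFrame) -> pd.DataFrame:
        """Per-subject nQi: arithmetic mean of the subject's window scores.

        Returns ``subject_id, n_windows, nqi``.  Subjects present in the
        table always have ≥ 1 window by construction; callers must
        report subjects that lost every window to the sparsity filter.
        """
        if len(features) == 0:
            raise ValueError("no retained windows to score")
        out = features.loc[:, ["subject_id"]].copy()
        out["score"] = self.predict_windows(features)
        grouped = out.groupby("subject_id", sort=True)["score"].agg(["size", "mean"])
        return (
            grouped.rename(columns={"size": "n_windows", "mean": "nqi"})
            .reset_index()
        )

    # -- reporting -----------------------------------------------------

    def summary(self) -> str:
        lines = [
            "nQi ensemble regression results",
            "=" * 46,
            f"members (N^m):        {self.n_models}",
            f"C:                    {self.C:g}",
            f"epsilon:              {self.epsilon:g}",
            f"bootstrap seed:       {self.seed}",
            f"standardized:         {self.feature_mean is not None}",
            f"training fingerprint: {self.training_fingerprint or 'n/a'}",
            "-" * 46,
            "feature        mean(w)      sd(w)",
        ]
        for j, name in enumerate(FEATURE_COLUMNS):
            lines.append(
                f"{name:<10} {self.weights[:, j].mean():>12.5f} "
                f"{self.weights[:, j].std():>10.5f}"
            )
        lines.append(
            f"{'bias':<10} {self.biases.mean():>12.5f} {self.biases.std():>10.5f}"
        )
        return "\n".join(lines)

    # -- serialization -------------------------------------------------

    def save(self, path) -> None:
        """Versioned JSON-text serialization of the fitted ensemble."""
        payload = {
            "format": "nqi-ensemble",
            "version": _SERIAL_VERSION,
            "C": self.C,
            "epsilon": self.epsilon,
            "n_models": self.n_models,
            "seed": self.seed,
            "target_normalization": f"updrs3/{UPDRS3_MAX}",
            "training_fingerprint": self.training_fingerprint,
            "feature_names": list(FEATURE_COLUMNS),
            "feature_mean": None if self.feature_mean is None else list(self.feature_mean),
            "feature_scale": None if self.feature_scale is None else list(self.feature_scale),
            "weights": self.weights.tolist(),
            "biases": self.biases.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "NQIResults":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "nqi-ensemble":
            raise ValueError("not an nQi ensemble file")
        return cls(
            model=None,
            weights=np.array(payload["weights"], dtype=float),
            biases=np.array(payload["biases"], dtype=float),
            feature_mean=None if payload["feature_mean"] is None
            else np.array(payload["feature_mean"]),
            feature_scale=None if payload["feature_scale"] is None
            else np.array(payload["feature_scale"]),
            training_fingerprint=payload.get("training_fingerprint", ""),
            C=payload["C"],
            epsilon=payload["epsilon"],
            seed=payload["seed"],
        )


def default_C_grid() -> np.ndarray:
    return np.logspace(-10, 4, 15, base=2.0)


def default_epsilon_grid() -> np.ndarray:
    return np.arange(0.01, 0.101, 0.01)


def grid_search_hyperparams(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    C_grid=None,
    eps_grid=None,
    *,
    n_models: int = 20,
    seed: int = DEFAULT_SEED,
) -> tuple[float, float, pd.DataFrame]:
    """Choose (C, ε) maximizing leave-one-subject-out AUC.

    For every grid pair, each subject in turn is held out, an ensemble
    is trained on the remaining subjects' windows, and the held-out
    subject's nQi is recorded; the AUC of the held-out scores against
    the PD/control labels scores that pair.  Ties break toward smaller
    C, then smaller ε.  Folds whose training set contains one class are
    skipped with a warning.

    Returns ``(C, epsilon, table)`` where ``table`` holds the full AUC
    grid (columns C, epsilon, auc).
    """
    import warnings

    from .evaluation import roc_auc

    C_grid = np.asarray(default_C_grid() if C_grid is None else C_grid, dtype=float)
    eps_grid = np.asarray(
        default_epsilon_grid() if eps_grid is None else eps_grid, dtype=float
    )
    if C_grid.size == 0 or eps_grid.size == 0:
        raise ValueError("empty hyperparameter grid")

    meta = metadata.set_index("subject_id")
    subjects = pd.unique(features["subject_id"].astype(str))
    labels_all = meta.loc[subjects, "group"].to_numpy()
    if len(set(labels_all)) < 2:
        raise ValueError("grid search needs both classes")

    rows = []
    for C in sorted(C_grid):
        for eps in sorted(eps_grid):
            held_scores, held_labels = [], []
            for s in subjects:
                train_feat = features.loc[features["subject_id"] != s]
                train_labels = meta.loc[
                    pd.unique(train_feat["subject_id"].astype(str)), "group"
                ]
                if train_labels.nunique() < 2:
                    warnings.warn(f"fold for subject {s} has one class; skipped")
                    continue
                res = NQIModel(
                    train_feat, metadata, C=C, epsilon=eps,
                    n_models=n_models, seed=seed,
                ).fit()
                test_feat = features.loc[features["subject_id"] == s]
                held_scores.append(
                    float(res.predict_windows(test_feat).mean())
                )
                held_labels.append(meta.loc[s, "group"])
            auc = roc_auc(np.array(held_scores), np.array(held_labels)).auc
            rows.append((float(C), float(eps), auc))
    table = pd.DataFrame(rows, columns=["C", "epsilon", "auc"])
    # stable argmax: rows are ordered by (C, eps) ascending, idxmax takes
    # the first maximum, i.e. smallest C then smallest epsilon
    best = table.loc[table["auc"].idxmax()]
    return float(best["C"]), float(best["epsilon"]), table
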