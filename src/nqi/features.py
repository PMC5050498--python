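"""Windowed featurization of hold-time series.

The hold-time signal is partitioned into non-overlapping square windows
of ``window_seconds`` (default 90 s), anchored at the first retained key
press.  Windows with fewer than ``min_samples`` hold times (default 30,
one third of the window length in seconds) are discarded: natural typing
comes in bursts separated by unpredictable pauses, and a near-empty
window carries no usable distributional information.

Each retained window B_i yields a 7-element feature vector

    x_i = (v_out, v_skew, h1, h2, h3, h4, v_de)

* ``v_out``  — fraction of hold times more than 1.5 interquartile ranges
  below the first or above the third quartile (Tukey outliers);
* ``v_skew`` — quartile skewness (q2 − q1) / (q3 − q1), in [0, 1];
* ``h1..h4`` — equally spaced normalized histogram over [0, 0.5) s
  (an approximation of the hold-time density; holds ≥ 0.5 s fall in no
  bin, so the bins sum to ≤ 1);
* ``v_de``   — finger coordination: for consecutive keystrokes the
  overlap release(first) − press(second), clamped at 0, averaged over
  the window's consecutive pairs.  Positive overlap means key rollover.

v_out, v_skew and v_de capture the dispersion and its dynamics — the
transient, heteroscedastic inflation of hold-time variance associated
with parkinsonian typing — while the histogram captures the absolute
hold-time distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .keystroke import HoldTimeSeries

__all__ = [
    "FEATURE_COLUMNS",
    "Window",
    "WindowConfig",
    "coordination_feature",
    "featurize",
    "featurize_series",
    "histogram_features",
    "outlier_fraction",
    "partition_windows",
    "quartile_skewness",
]

FEATURE_COLUMNS = ("v_out", "v_skew", "h1", "h2", "h3", "h4", "v_de")


class UndefinedFeatureError(ValueError):
    """A feature is requested on a window too small to define it."""


@dataclass(frozen=True)
class WindowConfig:
    """Windowing and feature parameters.

    ``min_samples`` defaults to ``window_seconds / 3`` — the sparsity
    filter threshold (30 for 90-s windows).
    """

    window_seconds: float = 90.0
    min_samples: int = None  # type: ignore[assignment]
    histogram_range: tuple[float, float] = (0.0, 0.5)
    histogram_bins: int = 4
    outlier_iqr_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.min_samples is None:
            object.__setattr__(self, "min_samples", int(self.window_seconds / 3))
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.histogram_bins < 1:
            raise ValueError("histogram_bins must be >= 1")


@dataclass
class Window:
    """One retained 90-s window: ordered hold times B_i plus timestamps."""

    index: int
    samples: np.ndarray        # hold times, press-time order
    press_times: np.ndarray
    release_times: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.press_times = np.asarray(self.press_times, dtype=float)
        self.release_times = np.asarray(self.release_times, dtype=float)

    def __len__(self) -> int:
        return self.samples.size


def partition_windows(series: HoldTimeSeries, cfg: WindowConfig = WindowConfig()) -> list[Window]:
    """Assign hold-time samples to half-open windows [i·w, (i+1)·w).

    Assignment is by press time only (a hold may extend past the window
    boundary); a press at exactly i·w belongs to window i.  Windows
    holding fewer than ``cfg.min_samples`` samples are dropped.
    """
    if series.is_empty:
        return []
    idx = np.floor(series.press_times / cfg.window_seconds).astype(int)
    windows: list[Window] = []
    for i in np.unique(idx):
        mask = idx == i
        if int(mask.sum()) < cfg.min_samples:
            continue
        windows.append(
            Window(
                index=int(i),
                samples=series.hold_times[mask],
                press_times=series.press_times[mask],
                release_times=series.release_times[mask],
            )
        )
    return windows


def _quartiles(samples: np.ndarray) -> tuple[float, float, float]:
    # type-7 rule: linear interpolation between order statistics
    q1, q2, q3 = np.percentile(samples, [25.0, 50.0, 75.0])
    return float(q1), float(q2), float(q3)


def outlier_fraction(samples, factor: float = 1.5) -> float:
    """Fraction of samples beyond ``factor`` IQRs outside [q1, q3]."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 4:
        raise UndefinedFeatureError("outlier_fraction needs >= 4 samples")
    q1, _, q3 = _quartiles(samples)
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    n_out = int(np.sum((samples < lo) | (samples > hi)))
    return n_out / samples.size


def quartile_skewness(samples) -> float:
    """Bowley's quartile skewness (q2 − q1)/(q3 − q1), mapped to [0, 1].

    0.5 means the median sits midway between the quartiles (symmetry).
    The degenerate case q3 == q1 (at least half the samples identical)
    returns the symmetric convention 0.5.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 4:
        raise UndefinedFeatureError("quartile_skewness needs >= 4 samples")
    q1, q2, q3 = _quartiles(samples)
    if q3 == q1:
        return 0.5
    return (q2 - q1) / (q3 - q1)


def histogram_features(samples, cfg: WindowConfig = WindowConfig()) -> np.ndarray:
    """Normalized histogram over half-open bins spanning ``histogram_range``.

    Bin k covers [lo + k·step, lo + (k+1)·step); samples at or beyond
    the upper range edge contribute to no bin, and the denominator is
    the *total* sample count, so the bins sum to ≤ 1 and long holds show
    up as missing mass.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 1:
        raise UndefinedFeatureError("histogram_features needs >= 1 sample")
    lo, hi = cfg.histogram_range
    step = (hi - lo) / cfg.histogram_bins
    idx = np.floor((samples - lo) / step).astype(int)
    in_range = (samples >= lo) & (samples < hi)
    counts = np.bincount(idx[in_range], minlength=cfg.histogram_bins)
    return counts[: cfg.histogram_bins] / samples.size


def coordination_feature(press_times, release_times) -> float:
    """Mean clamped key-rollover overlap across consecutive keystrokes.

    For each consecutive pair (press-time order) the overlap is
    release(first) − press(second); negative values (strictly sequential
    typing) clamp to 0.  A window with fewer than two keystrokes has no
    pair and returns 0.
    """
    press = np.asarray(press_times, dtype=float)
    release = np.asarray(release_times, dtype=float)
    if press.size < 2:
        return 0.0
    overlap = release[:-1] - press[1:]
    return float(np.mean(np.clip(overlap, 0.0, None)))


def featurize(window: Window, cfg: WindowConfig = WindowConfig()) -> np.ndarray:
    """Assemble the 7-vector (v_out, v_skew, h1..h4, v_de) for one window."""
    h = histogram_features(window.samples, cfg)
    return np.array(
        [
            outlier_fraction(window.samples, cfg.outlier_iqr_factor),
            quartile_skewness(window.samples),
            *h,
            coordination_feature(window.press_times, window.release_times),
        ]
    )


def featurize_series(
    series: HoldTimeSeries, cfg: WindowConfig = WindowConfig()
) -> pd.DataFrame:
    """Partition a subject's hold-time series and featurize each window.

    Returns the canonical feature table with columns
    ``subject_id, window_index, v_out, v_skew, h1..h4, v_de, n_samples``
    (empty, correctly typed, if no window survives the filter).
    """
    rows = []
    for w in partition_windows(series, cfg):
        x = featurize(w, cfg)
        rows.append((series.subject_id, w.index, *x, len(w)))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "window_index", *FEATURE_COLUMNS, "n_samples"],
    ).astype({"window_index": int, "n_samples": int}, errors="ignore")
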