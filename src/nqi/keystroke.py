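"""Keystroke event logs and derived hold-time series.

The raw signal is a sequence of key press/release timestamp pairs per
subject.  The quantity of interest is the *hold time* (HT): the interval
between pressing and releasing a single key, typically on the order of
100 ms during natural typing.  Only keys for which a short hold is
expected — alphanumerics, printable symbols and the space bar — carry
signal; modifier and navigation keys are held intentionally long and are
excluded before any analysis.

Canonical on-disk formats are plain CSV:

* event file:    ``subject_id,key,press_time,release_time`` (seconds,
  decimal point; optional ``key_class`` column overrides automatic
  classification)
* metadata file: ``subject_id,group,updrs3,age,sex,education_years,
  typing_speed,dataset_tag``
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ELIGIBLE_CLASSES",
    "HoldTimeSeries",
    "classify_key",
    "compute_hold_times",
    "read_events",
    "read_metadata",
    "write_events",
]

#: Key classes whose hold times enter the analysis.
ELIGIBLE_CLASSES = frozenset({"alphanumeric", "symbol", "space"})

# Modifier / navigation / editing keys: held deliberately, not reflex
# hold times.  Backspace and delete are excluded too (documented choice;
# flip by passing an explicit key_class column).
_OTHER_KEYS = frozenset(
    {
        "shift", "shift_l", "shift_r", "ctrl", "control", "ctrl_l", "ctrl_r",
        "alt", "alt_l", "alt_r", "altgr", "meta", "cmd", "super", "win",
        "capslock", "caps_lock", "numlock", "num_lock", "scrolllock",
        "esc", "escape", "tab", "enter", "return", "backspace", "delete",
        "del", "insert", "ins", "home", "end", "pageup", "page_up",
        "pagedown", "page_down", "up", "down", "left", "right",
        "arrowup", "arrowdown", "arrowleft", "arrowright", "menu",
        "pause", "printscreen", "print_screen", "fn",
    }
    | {f"f{i}" for i in range(1, 25)}
)

_SPACE_KEYS = frozenset({" ", "space", "spacebar", "space_bar"})

REQUIRED_EVENT_COLUMNS = ("subject_id", "key", "press_time", "release_time")
METADATA_COLUMNS = (
    "subject_id", "group", "updrs3", "age", "sex",
    "education_years", "typing_speed", "dataset_tag",
)


class EventFormatError(ValueError):
    """Raised when an event or metadata file violates the canonical schema."""


def classify_key(label: str) -> str:
    """Classify a key label into alphanumeric / symbol / space / other.

    Single printable characters are alphanumeric or symbol; named keys
    are matched case-insensitively against the modifier/navigation set.
    Unrecognised multi-character names default to ``other`` — when in
    doubt a key is kept out of the hold-time signal.
    """
    name = str(label)
    lowered = name.strip().lower()
    if name in _SPACE_KEYS or lowered in _SPACE_KEYS:
        return "space"
    if lowered in _OTHER_KEYS:
        return "other"
    if len(name) == 1:
        if name.isalnum():
            return "alphanumeric"
        if name.isprintable() and not name.isspace():
            return "symbol"
        return "other"
    if name.isalnum():  # named digits/letters e.g. "KP_5"-style left out
        return "alphanumeric"
    return "other"


@dataclass
class HoldTimeSeries:
    """Hold-time signal a[t] for one subject.

    ``press_times`` and ``hold_times`` are parallel arrays ordered by
    non-decreasing press time and contain only eligible key classes;
    ``release_times`` (press + hold) are kept because the finger
    coordination feature needs consecutive press/release pairs.
    """

    subject_id: str
    press_times: np.ndarray
    hold_times: np.ndarray
    source_event_count: int = 0
    release_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.press_times = np.asarray(self.press_times, dtype=float)
        self.hold_times = np.asarray(self.hold_times, dtype=float)
        if self.release_times is None:
            self.release_times = self.press_times + self.hold_times
        else:
            self.release_times = np.asarray(self.release_times, dtype=float)
        if self.press_times.shape != self.hold_times.shape:
            raise ValueError("press_times and hold_times must be parallel")
        if np.any(np.diff(self.press_times) < 0):
            raise ValueError("press times must be non-decreasing")
        if np.any(self.hold_times < 0):
            raise ValueError("hold times must be non-negative")

    def __len__(self) -> int:
        return self.press_times.size

    @property
    def is_empty(self) -> bool:
        return len(self) == 0


def read_events(path, *, dialect: dict | None = None) -> pd.DataFrame:
    """Read a keystroke event file into a tidy DataFrame.

    Returns a frame with columns ``subject_id, key, press_time,
    release_time, key_class`` sorted by subject then press time.  Rows
    with release before press are dropped; the number of rejected rows
    is attached as ``df.attrs["n_rejected"]`` and reported via a
    warning.

    Parameters
    ----------
    dialect
        Optional overrides passed to :func:`pandas.read_csv`
        (e.g. ``{"sep": "\\t"}``).
    """
    kwargs = {"sep": ","}
    if dialect:
        kwargs.update(dialect)
    df = pd.read_csv(path, **kwargs)
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventFormatError(f"event file missing columns: {missing}")
    df["subject_id"] = df["subject_id"].astype(str)
    df["press_time"] = df["press_time"].astype(float)
    df["release_time"] = df["release_time"].astype(float)

    bad = (df["release_time"] < df["press_time"]) | (df["press_time"] < 0)
    n_rejected = int(bad.sum())
    if n_rejected:
        warnings.warn(
            f"{n_rejected} malformed event row(s) rejected "
            "(release before press or negative press time)",
            stacklevel=2,
        )
        df = df.loc[~bad]

    if "key_class" not in df.columns:
        df["key_class"] = df["key"].map(classify_key)
    else:
        df["key_class"] = df["key_class"].fillna(df["key"].map(classify_key))

    df = df.sort_values(["subject_id", "press_time"], kind="mergesort")
    df = df.reset_index(drop=True)
    df.attrs["n_rejected"] = n_rejected
    return df


def write_events(df: pd.DataFrame, path) -> None:
    """Write events in the canonical CSV dialect (comma, header, UTF-8)."""
    cols = [c for c in (*REQUIRED_EVENT_COLUMNS, "key_class") if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def read_metadata(path) -> pd.DataFrame:
    """Read the per-subject metadata table.

    Validates the diagnostic group labels and the UPDRS-III range
    (0–108, the motor-section maximum).
    """
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise EventFormatError(f"metadata file missing columns: {missing}")
    df["subject_id"] = df["subject_id"].astype(str)
    bad_group = ~df["group"].isin(["PD", "control"])
    if bad_group.any():
        raise EventFormatError(
            f"unknown group labels: {sorted(df.loc[bad_group, 'group'].unique())}"
        )
    if (df["updrs3"] < 0).any() or (df["updrs3"] > 108).any():
        raise EventFormatError("updrs3 outside the 0-108 scale")
    return df


def compute_hold_times(
    events: pd.DataFrame,
    eligible: frozenset[str] | set[str] = ELIGIBLE_CLASSES,
) -> HoldTimeSeries:
    """Derive the hold-time series for a single subject's events.

    One (press_time, hold_time) sample per eligible event, in press-time
    order; hold = release − press.  Timestamps are re-anchored so that
    t = 0 is the first *retained* key press.  An empty result (no
    eligible events) is valid and flagged via ``is_empty``.
    """
    subjects = events["subject_id"].unique()
    if len(subjects) > 1:
        raise ValueError(
            "compute_hold_times expects events for one subject; "
            f"got {len(subjects)}"
        )
    subject_id = str(subjects[0]) if len(subjects) else ""

    if "key_class" not in events.columns:
        events = events.assign(key_class=events["key"].map(classify_key))
    kept = events.loc[events["key_class"].isin(eligible)]
    kept = kept.sort_values("press_time", kind="mergesort")
    press = kept["press_time"].to_numpy(dtype=float)
    release = kept["release_time"].to_numpy(dtype=float)
    if press.size:
        origin = press[0]
        press = press - origin
        release = release - origin
    return HoldTimeSeries(
        subject_id=subject_id,
        press_times=press,
        hold_times=release - press,
        release_times=release,
        source_event_count=len(events),
    )
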