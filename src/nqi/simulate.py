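"""Synthetic keystroke cohorts with PD-like hold-time dynamics.

The generator emulates the statistical structure the nQi method relies
on, so the whole pipeline can be exercised end-to-end without clinical
data:

* **Burst–pause typing.**  Sessions of ~14 min (sd 2.9) consist of key
  bursts (geometric length, mean ~15 keys) separated by pauses; rare
  long pauses (40–150 s) leave some 90-s windows under the 30-sample
  sparsity threshold, exercising the window filter.
* **Hold times.**  Lognormal with a subject-specific location around
  100 ms; for controls essentially homoscedastic, with >95% of holds
  inside 0–500 ms.
* **PD-like heteroscedasticity.**  A two-state Markov regime process
  per subject intermittently inflates the lognormal shape by a factor
  1 + severity·severity_effect and injects extra heavy-tail holds
  (mass above 0.3 s).  The signal is *transient variance*, not a mean
  shift — discriminability vanishes as ``severity_effect → 0`` even
  though diagnostic labels and UPDRS-III still differ.
* **Severity ↔ UPDRS-III.**  A latent severity in [0, 1] drives both
  the typing dynamics and a synthetic UPDRS-III ≈ 108·severity·0.38
  plus noise, putting PD means near 20 and controls near 2 on the
  0–108 scale.
* **Covariates** (age, sex, education, typing speed) are drawn from
  the same distributions in both groups, so covariate-adjusted tests
  see the no-confounding case.

What this does *not* emulate: real key-identity sequences, linguistic
content, error/backspace behaviour, medication state or any
non-motor comorbidity — passing tests show the pipeline recovers the
planted variance signal, not that it generalises to clinic data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "simulate_cohort", "simulate_subject"]

_LETTERS = list("abcdefghijklmnopqrstuvwxyz0123456789")
_INELIGIBLE = ["shift", "backspace", "enter"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort generator."""

    n_pd: int = 20
    n_control: int = 20
    session_minutes_mean: float = 14.0
    session_minutes_sd: float = 2.9
    base_hold_ms: float = 100.0       # lognormal median for controls
    hold_sigma: float = 0.35          # lognormal shape (log-scale sd)
    subject_sigma: float = 0.15       # between-subject spread of log-location
    severity_effect: float = 1.0      # variance-inflation slope
    outlier_rate_pd: float = 0.3      # heavy-tail prob in inflated state at effect 1
    burst_mean_keys: float = 15.0
    pause_mean_s: float = 2.5
    long_pause_prob: float = 0.02
    long_pause_range_s: tuple[float, float] = (40.0, 120.0)
    typing_speed_range: tuple[float, float] = (70.0, 150.0)  # keys/min target
    ineligible_key_rate: float = 0.05
    updrs_scale: float = 0.38         # UPDRS-III ≈ 108·severity·scale
    updrs_noise_sd: float = 1.5
    pd_severity_range: tuple[float, float] = (0.25, 0.75)
    control_severity_range: tuple[float, float] = (0.0, 0.09)
    # regime-switching transition probabilities per keystroke
    p_enter_inflated: float = 0.02
    p_exit_inflated: float = 0.05
    seed: int = 20161005

    def __post_init__(self) -> None:
        if min(self.n_pd, self.n_control) < 0:
            raise ValueError("subject counts must be non-negative")
        if self.base_hold_ms <= 0 or self.pause_mean_s <= 0:
            raise ValueError("rates must be positive")


def simulate_subject(
    cfg: SimConfig,
    group: str,
    severity: float,
    subject_id: str,
    rng: np.random.Generator,
) -> tuple[dict, pd.DataFrame]:
    """Generate one subject's metadata row and keystroke event stream.

    ``severity`` in [0, 1] scales both the typing-variance regime and
    the synthetic UPDRS-III.  Deterministic given the generator state.
    """
    if not 0 <= severity <= 1:
        raise ValueError("severity must lie in [0, 1]")
    effect = severity * cfg.severity_effect
    sigma_inflated = cfg.hold_sigma * (1.0 + effect)
    p_outlier = cfg.outlier_rate_pd * min(1.0, effect)

    mu_subj = np.log(cfg.base_hold_ms / 1000.0) + rng.normal(0, cfg.subject_sigma)
    # clip at roughly mean ± 2 sd: keeps the 14 (2.9) min regime while
    # guaranteeing enough 90-s windows for a stable subject score
    session_s = float(
        np.clip(rng.normal(cfg.session_minutes_mean, cfg.session_minutes_sd), 8.0, 20.0)
    ) * 60.0

    # within-burst inter-key interval from the target overall typing rate:
    # rate = L / (L·iki + P)  =>  iki = 1/r − P/L
    speed_target = rng.uniform(*cfg.typing_speed_range)  # keys/min
    r = speed_target / 60.0
    iki_median = max(0.08, 1.0 / r - cfg.pause_mean_s / cfg.burst_mean_keys)

    rows: list[tuple] = []
    t = 0.0
    state = 0  # 0 normal, 1 inflated variance
    while t < session_s:
        burst_len = 1 + rng.geometric(1.0 / cfg.burst_mean_keys)
        for _ in range(burst_len):
            if t >= session_s:
                break
            if state == 0:
                if rng.random() < cfg.p_enter_inflated:
                    state = 1
            else:
                if rng.random() < cfg.p_exit_inflated:
                    state = 0
            if state == 1 and rng.random() < p_outlier:
                ht = rng.lognormal(np.log(0.35), 0.3)
            else:
                sigma = sigma_inflated if state == 1 else cfg.hold_sigma
                ht = rng.lognormal(mu_subj, sigma)
            if rng.random() < cfg.ineligible_key_rate:
                key = _INELIGIBLE[rng.integers(len(_INELIGIBLE))]
                ht = rng.uniform(0.1, 1.5)  # modifiers held deliberately long
            else:
                key = _LETTERS[rng.integers(len(_LETTERS))] if rng.random() > 0.18 else " "
            rows.append((subject_id, key, round(t, 4), round(t + ht, 4)))
            t += rng.lognormal(np.log(iki_median), 0.4)
        if rng.random() < cfg.long_pause_prob:
            t += rng.uniform(*cfg.long_pause_range_s)
        else:
            t += rng.exponential(cfg.pause_mean_s)

    events = pd.DataFrame(
        rows, columns=["subject_id", "key", "press_time", "release_time"]
    )
    updrs = int(
        np.clip(
            round(108 * severity * cfg.updrs_scale + rng.normal(0, cfg.updrs_noise_sd)),
            0,
            108,
        )
    )
    realized_speed = len(rows) / (session_s / 60.0)
    meta = {
        "subject_id": subject_id,
        "group": group,
        "updrs3": updrs,
        "age": float(np.clip(round(rng.normal(59.5, 10.0), 1), 30, 90)),
        "sex": "F" if rng.random() < 0.5 else "M",
        "education_years": float(np.clip(round(rng.normal(15.0, 4.5), 1), 6, 25)),
        "typing_speed": round(realized_speed, 2),
        "dataset_tag": "other",
        "severity": round(float(severity), 4),
    }
    return meta, events


def simulate_cohort(
    cfg: SimConfig,
    dataset_tag: str = "other",
    subject_prefix: str = "S",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort; returns (events, metadata) DataFrames.

    Controls draw severities near zero, PD subjects across the
    configured spread; UPDRS-III group means land near the 20.6 / 1.9
    regime of an early-PD case/control cohort.  Reproducible given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    metas, event_frames = [], []
    specs = [("PD", cfg.pd_severity_range, cfg.n_pd), ("control", cfg.control_severity_range, cfg.n_control)]
    k = 0
    for group, sev_range, count in specs:
        for _ in range(count):
            severity = float(rng.uniform(*sev_range))
            sid = f"{subject_prefix}{k:03d}"
            meta, events = simulate_subject(cfg, group, severity, sid, rng)
            meta["dataset_tag"] = dataset_tag
            metas.append(meta)
            event_frames.append(events)
            k += 1
    metadata = pd.DataFrame(metas)
    events = pd.concat(event_frames, ignore_index=True)
    return events, metadata


def simulate_cohort_files(cfg: SimConfig, events_path, metadata_path,
                          dataset_tag: str = "other", subject_prefix: str = "S") -> None:
    """Write a simulated cohort in the canonical CSV formats."""
    events, metadata = simulate_cohort(cfg, dataset_tag, subject_prefix)
    events.to_csv(events_path, index=False)
    metadata.to_csv(metadata_path, index=False)


def null_config(cfg: SimConfig) -> SimConfig:
    """The matched null condition: no typing effect of disease.

    Severity still drives UPDRS-III and labels, but the variance regime
    is disabled, so typing is exchangeable between groups.
    """
    return replace(cfg, severity_effect=0.0)
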