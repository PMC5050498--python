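import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from nqi.features import featurize_series
from nqi.keystroke import compute_hold_times
from nqi.simulate import SimConfig, simulate_cohort


def featurize_cohort(events: pd.DataFrame) -> pd.DataFrame:
    """Window features for every subject of an event table."""
    return pd.concat(
        [
            featurize_series(compute_hold_times(group))
            for _, group in events.groupby("subject_id", sort=True)
        ],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort (8 PD / 8 controls) with features."""
    cfg = SimConfig(n_pd=8, n_control=8, seed=7)
    events, metadata = simulate_cohort(cfg, dataset_tag="early_pd")
    features = featurize_cohort(events)
    return events, metadata, features


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """A small fitted ensemble on the compact cohort."""
    from nqi.model import NQIModel

    _, metadata, features = small_cohort
    res = NQIModel(features, metadata, n_models=24, seed=11).fit()
    return res, features, metadata
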