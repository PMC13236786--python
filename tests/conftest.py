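import numpy as np
import pandas as pd
import pytest

from gazecnn import SynthConfig, default_geometry, generate
from gazecnn.io import Dataset


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()  # 2560x1440, horizontal meridian


@pytest.fixture(scope="session")
def small_dataset():
    """Small capture-present synthetic cohort shared across tests."""
    return generate(SynthConfig(n_participants=6, trials_per_participant=60, seed=5))


@pytest.fixture()
def three_trial_dataset(geometry):
    """Hand-built 3-trial dataset with missing cells and an absent distractor."""
    trials = pd.DataFrame(
        {
            "participant_id": ["p1", "p1", "p2"],
            "trial_index": [1, 2, 1],
            "target_location": [0, 4, 2],
            "distractor_location": [3.0, np.nan, 5.0],
            "rt_ms": [640.0, np.nan, 1200.0],
            "n_recorded_samples": [3, 2, 4],
        }
    )
    traces = {
        ("p1", 1): np.array([[1279.5, 719.5], [np.nan, 700.0], [1300.0, np.nan]]),
        ("p1", 2): np.array([[100.25, 200.5], [101.0, 201.0]]),
        ("p2", 1): np.array([[np.nan, np.nan]] * 4),
    }
    return Dataset(geometry=geometry, trials=trials, traces=traces)


def dense_trials(n_participants: int, n_trials: int, half_distractor: bool = False) -> pd.DataFrame:
    """Metadata-only trial table with dense trial indices (no traces needed)."""
    rng = np.random.default_rng(0)
    pids = np.repeat([f"p{i:03d}" for i in range(n_participants)], n_trials)
    tidx = np.tile(np.arange(1, n_trials + 1), n_participants)
    target = rng.integers(0, 6, size=pids.size)
    distractor = np.full(pids.size, np.nan)
    if half_distractor:
        present = tidx <= n_trials // 2  # deterministic half
        shift = rng.integers(1, 6, size=pids.size)
        distractor[present] = (target[present] + shift[present]) % 6
    return pd.DataFrame(
        {
            "participant_id": pids,
            "trial_index": tidx,
            "target_location": target,
            "distractor_location": distractor,
            "rt_ms": 600.0,
            "n_recorded_samples": 300,
        }
    )
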