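import warnings

import numpy as np
import pytest

from gaittrait import (
    CohortConfig,
    GaitSegment,
    WalkerParams,
    preprocess_sequence,
    simulate_cohort,
    simulate_walker,
)
from gaittrait.errors import GaitWarning


@pytest.fixture(autouse=True)
def _quiet_gait_warnings():
    # generator / data-quality warnings are expected throughout the suite
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", GaitWarning)
        yield


@pytest.fixture(scope="session")
def default_walker_segment() -> GaitSegment:
    """One preprocessed 75-frame segment from the default synthetic walker."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", GaitWarning)
        seq = simulate_walker(WalkerParams(seed=42), seconds=120, fps=25)
        seq.participant_id = "walker42"
        return preprocess_sequence(seq)


@pytest.fixture()
def random_segment():
    """Factory for small random-walk segments of arbitrary length."""

    def make(n_frames: int = 75, seed: int = 0) -> GaitSegment:
        rng = np.random.default_rng(seed)
        data = np.cumsum(rng.normal(size=(n_frames, 24, 2)), axis=0)
        return GaitSegment(data, fps=25.0, participant_id=f"rand{seed}")

    return make


@pytest.fixture(scope="session")
def tiny_cohort():
    """Fast 8-walker cohort with short bouts for plumbing tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", GaitWarning)
        return simulate_cohort(CohortConfig(n_walkers=8, seed=3, bout_seconds=20.0))
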