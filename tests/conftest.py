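import numpy as np
import pytest

from soundscape_trf import (
    generate_event_train,
    make_triphasic_kernel,
    synthesize_eeg,
    events_to_markers,
)
from soundscape_trf.features import FeatureSet

EEG_RATE = 100.0

# short grid for module tests; acceptance tests use the full default grid
QUICK_LAMBDAS = (0.1, 10.0, 1000.0)


@pytest.fixture(scope="session")
def kernel():
    return make_triphasic_kernel(EEG_RATE)


@pytest.fixture(scope="session")
def small_events():
    return generate_event_train(120.0, 80, min_gap_s=0.6, seed=11)


@pytest.fixture(scope="session")
def small_eeg(small_events, kernel):
    return synthesize_eeg(
        small_events, kernel, snr_db=5.0, n_channels=8, eeg_rate=EEG_RATE,
        duration_s=120.0, seed=12,
    )


def onset_feature(events, n_samples, rate=EEG_RATE) -> FeatureSet:
    """Single pooled binary onset column from an event table."""
    markers = events_to_markers(events, n_samples, rate)
    col = (markers.data.sum(axis=1) > 0).astype(float)
    return FeatureSet(col[:, None], ["onsets"], [True], rate)


@pytest.fixture(scope="session")
def small_onsets(small_events, small_eeg):
    return onset_feature(small_events, small_eeg.n_samples)
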