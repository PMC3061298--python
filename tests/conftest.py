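import numpy as np
import pytest

from biosigkit.synth_fixtures import (
    make_eeg_eog_mixture,
    make_mvar_process,
    make_synth_ecg,
)


@pytest.fixture(scope="session")
def eeg_eog_mixture():
    """Default EOG-contamination scenario (session-scoped: T=1e5 is costly)."""
    return make_eeg_eog_mixture()


@pytest.fixture(scope="session")
def chain_mvar():
    """Three-channel chain 1→2→3 MVAR fixture."""
    return make_mvar_process(scenario="chain")


@pytest.fixture(scope="session")
def ecg_60bpm():
    """Clean 60-bpm, 60-s impulse-train ECG."""
    return make_synth_ecg()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
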