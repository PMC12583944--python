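import numpy as np
import pytest

from hyperti import synthetic


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def zero_lag_spec():
    """A quiet 60-s session: no artifacts, no lags, no injected coherence."""
    return synthetic.SessionSpec(
        duration=60.0,
        band_coherence={},
        artifact_rate=0.0,
        audio_lags_ms={s: 0.0 for s in synthetic.subject_ids()},
        seed=101,
    )


@pytest.fixture(scope="session")
def quiet_recordings(zero_lag_spec):
    recs, truth = synthetic.generate_eeg_session(zero_lag_spec)
    return recs, truth
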