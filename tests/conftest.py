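import numpy as np
import pytest

from silenttrack.synthgen import CohortSpec, make_speech_envelope


@pytest.fixture(scope="session")
def envelope_120s():
    """One 120-s speech envelope at the analysis rate."""
    return make_speech_envelope(duration=120.0, rate=150.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_spec():
    """Tiny single-group cohort spec for fast unit tests."""
    return CohortSpec(n_per_group={"hearing": 2}, duration=60.0,
                      n_neural=1, seed=1)
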