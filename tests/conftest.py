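import numpy as np
import pytest

from ausculta.simulate import BreathCycleSpec, compose_recording, generate_corpus
from ausculta.phenomena import PhenomenonEvent


@pytest.fixture(scope="session")
def tiny_corpus():
    """Eight short recordings with known labels, shared across tests."""
    recordings, manifest = generate_corpus(8, seed=42, duration=4.0)
    return recordings, manifest


@pytest.fixture(scope="session")
def wheeze_recording():
    """One 5 s recording with a single wheeze at [1.0, 1.2) s."""
    ev = PhenomenonEvent("wheeze", 1.0, 1.2, f0=400.0)
    return compose_recording(5.0, event_plan=[ev], seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
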