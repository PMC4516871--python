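import numpy as np
import pytest

from alphapress.simulate import SimulatedSubject, run_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def session_with_signals():
    """One moderate closed-loop session with synthesized epochs (shared)."""
    return run_session(220, SimulatedSubject(), seed=42)


@pytest.fixture(scope="session")
def long_behavior_session():
    """A long behavior-only session for behavioral statistics (shared)."""
    return run_session(2500, SimulatedSubject(), seed=7, synthesize_signals=False)
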