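import numpy as np
import pytest

from attractorchoice.attractor import AttractorParams
from attractorchoice.valuation import ParticipantProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def profile():
    """A plausible fitted profile (non-increasing indifference points)."""
    return ParticipantProfile(
        indifference_points={1: 0.90, 4: 0.72, 8: 0.55, 12: 0.45}
    )


@pytest.fixture
def quiet_params():
    """Noiseless dynamics for deterministic integration checks."""
    return AttractorParams(noise_sd=0.0, iti_noise_sd=0.0)
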