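import numpy as np
import pytest

from pulsecnn.synthetic import (
    DATASET1_SPECS,
    Jitter,
    PulseClassSpec,
    PulseComponentSpec,
    generate_record,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def h1_spec():
    return DATASET1_SPECS["H1"]


@pytest.fixture
def single_bump_spec():
    """One Gaussian component, no jitter: closed-form oracle material."""
    return PulseClassSpec(
        "bump",
        (PulseComponentSpec(1.0, 0.2, 0.05),),
        Jitter(0.0, 0.0, 0.0),
    )


@pytest.fixture
def clean_record(h1_spec):
    """A 10-cycle noise-free record with known boundaries."""
    return generate_record(h1_spec, 10, noise_sd=0.0, wander_amplitude=0.0,
                           rng=np.random.default_rng(7), subject_id="S1")


@pytest.fixture
def noisy_record(h1_spec):
    """A 10-cycle record at 20 dB SNR with mild baseline wander."""
    return generate_record(h1_spec, 10, noise_sd=0.1, wander_amplitude=0.05,
                           rng=np.random.default_rng(7), subject_id="S1")
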