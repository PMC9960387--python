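import numpy as np
import pytest

from edapain.synth import SimParams, desk_protocol, generate_dataset


@pytest.fixture(scope="session")
def small_windowset():
    """8 subjects x 2 labels x 2 reps at 32 Hz / 10 s: cheap but structured."""
    return generate_dataset(desk_protocol(n_subjects=8, reps_per_label=2), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def quiet_params():
    """Noise-free, deterministic simulation parameters (no spontaneous SCRs,
    no measurement noise, no tonic wander)."""
    return SimParams(p_spont=0.0, noise_sd=0.0, wander_sd=0.0)
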