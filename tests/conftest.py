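import numpy as np
import pytest

from mibci import synth


@pytest.fixture(scope="session")
def montage250():
    return synth.MontageSpec(fs=250.0)


@pytest.fixture(scope="session")
def small_recording(montage250):
    """1 session x 1 run x 3 reps/class at 250 Hz: 12 trials, ~75 s."""
    return synth.simulate_recording(1, 1, 3, montage=montage250, seed=42)


@pytest.fixture(scope="session")
def medium_recording(montage250):
    """1 session x 2 runs x 8 reps/class at 250 Hz: 64 trials."""
    return synth.simulate_recording(1, 2, 8, montage=montage250, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
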