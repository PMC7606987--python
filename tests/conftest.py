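import numpy as np
import pytest

from cerevasc.synthetic import PhantomSpec, synthesize_subject


@pytest.fixture(scope="session")
def young_subject():
    """Noiseless default young-adult phantom, shared across read-only tests."""
    return synthesize_subject(PhantomSpec(seed=11, noise_sigma=0.0))


@pytest.fixture(scope="session")
def noisy_subject():
    """Default young-adult phantom with calibrated noise."""
    return synthesize_subject(PhantomSpec(seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
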