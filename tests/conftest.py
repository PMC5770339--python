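import numpy as np
import pytest

from neuropipe.phantom import PhantomParams, generate_t1_bundle


@pytest.fixture(scope="session")
def clean_bundle():
    """One clean default phantom, shared read-only across tests."""
    return generate_t1_bundle(PhantomParams(seed=11))


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Noise-free, bias-free phantom: piecewise-constant tissue intensities."""
    return generate_t1_bundle(
        PhantomParams(noise_sigma=0.0, bias_amplitude=0.0, seed=11))
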