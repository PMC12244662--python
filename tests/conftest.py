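import numpy as np
import pytest

from gcfuse.phantoms import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_small():
    """One noiseless 96x96 CT/MR-like pair with its geometry masks."""
    return generate_phantom(PhantomSpec(size=(96, 96), seed=42, noise_sigma=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
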