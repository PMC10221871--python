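import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_batch():
    """Small shared phantom set for pipeline-level tests."""
    from boneage.phantoms import generate_samples

    return generate_samples(24, seed=0)
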