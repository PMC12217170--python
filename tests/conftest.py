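import dataclasses

import numpy as np
import pytest

from blcb.synth import SynthConfig, generate_image


@pytest.fixture(scope="session")
def sample():
    """One default-size (256x256) synthetic fundus sample."""
    return generate_image(SynthConfig(seed=3))


@pytest.fixture(scope="session")
def small_sample():
    """A 128x128 sample for tests where speed matters more than scale."""
    return generate_image(SynthConfig(height=128, width=128, seed=5))


@pytest.fixture(scope="session")
def sample_batch():
    """Five default-size samples with distinct seeds."""
    return [
        generate_image(dataclasses.replace(SynthConfig(), seed=s))
        for s in (11, 12, 13, 14, 15)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
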