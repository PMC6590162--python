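import numpy as np
import pytest

from hetci.tau2 import MetaSample


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


@pytest.fixture
def simple_sample():
    """The two-study textbook sample: Q(tau2) = 2 / (1 + tau2)."""
    return MetaSample(y=[0.0, 2.0], var=[1.0, 1.0])


@pytest.fixture
def random_samples(rng):
    """A batch of irregular samples spanning k and variance spread."""
    samples = []
    for k in (2, 3, 5, 8, 20):
        for _ in range(3):
            var = rng.uniform(0.05, 2.0, size=k)
            y = rng.normal(0.3, 0.8, size=k)
            samples.append(MetaSample(y=y, var=var))
    return samples
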