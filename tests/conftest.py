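import numpy as np
import pytest

from apicalnet.synthetic import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom3():
    """A three-tooth unrotated phantom with its truth."""
    spec = PhantomSpec(n_teeth=3, lesion_flags=(False, True, False), seed=7)
    image, truth = generate_phantom(spec)
    return spec, image, truth
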