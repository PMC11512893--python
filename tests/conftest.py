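import numpy as np
import pytest

from spinalzfnet import phantom


@pytest.fixture(scope="session")
def clean_samples():
    """Noise-free phantoms, two per class, 64 px."""
    spec = phantom.PhantomSpec(image_size=64, n_per_class=2, seed=7,
                               noise_sd=0.0, impulse_frac=0.0)
    return phantom.generate(spec)


@pytest.fixture(scope="session")
def noisy_samples():
    """Default-noise phantoms, five per class, 64 px."""
    spec = phantom.PhantomSpec(image_size=64, n_per_class=5, seed=11)
    return phantom.generate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
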