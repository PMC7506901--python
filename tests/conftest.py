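import numpy as np
import pytest

from cspdecode import (
    BandPassSpec,
    SyntheticConfig,
    bandpass_epochs,
    generate_epochs,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_epochs():
    """A small discriminative two-class set (shared across read-only tests)."""
    cfg = SyntheticConfig(n_trials_per_class=20, seed=42)
    epochs, truth = generate_epochs(cfg)
    return epochs, truth


@pytest.fixture(scope="session")
def filtered_epochs(small_epochs):
    epochs, truth = small_epochs
    return bandpass_epochs(epochs, BandPassSpec(8.0, 30.0, order=6)), truth


def random_spd(rng, n, scale=1.0):
    a = rng.standard_normal((n, n))
    m = a @ a.T + n * np.eye(n)
    return scale * m / np.trace(m)
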