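import numpy as np
import pytest

from nirpls import SimConfig, SpectraMatrix, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_spectra():
    """Tiny well-formed matrix on a 3-decimal-exact grid."""
    nu = np.round(4000.0 + 4.0 * np.arange(5), 3)
    return SpectraMatrix(
        ["a", "b"], nu,
        [[0.1, 0.2, 0.3, 0.4, 0.5], [1.0, 0.9, 0.7, 0.4, 0.0]],
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic study shared across tests (60 samples, default grid)."""
    config = SimConfig(n_samples=60, seed=11)
    spectra, composition, reactivity = simulate_dataset(config)
    return config, spectra, composition, reactivity
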