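import numpy as np
import pytest

from cortexmap import synthetic


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_activations():
    """Mixture of 5 Laplace sources in 60 units, mild noise."""
    return synthetic.gen_latent_sources(2000, 60, 5, noise_sd=0.1, seed=1)


@pytest.fixture(scope="session")
def two_gradient_map():
    """Two orthogonal planted gradients (1.5 and 4.5 cycles) plus mild noise."""
    e = np.eye(25)
    g1 = synthetic.GradientSpec(axis=e[0], frequency=1.5, orientation_deg=0.0)
    g2 = synthetic.GradientSpec(axis=e[1], frequency=4.5, orientation_deg=-90.0)
    return synthetic.gen_gradient_map(
        np.ones((30, 30), bool), [g1, g2], noise_amplitude=0.3, seed=7
    )


def unit_rows(M):
    return M / np.linalg.norm(M, axis=1, keepdims=True)
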