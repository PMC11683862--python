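import numpy as np
import pytest

from lfer2p import GeneratorSpec, generate_chemicals, generate_observations


def make_table(n=51, sigma=0.3, seed=0, correlation=0.0, descriptors=False,
               truth=(0.851, -0.092, -1.080), phase="structural_protein"):
    spec = GeneratorSpec(
        n=n, noise_sigma=sigma, seed=seed, correlation=correlation,
        include_descriptors=descriptors, true_coefficients=truth,
    )
    return generate_observations(generate_chemicals(spec), spec, phase)


@pytest.fixture
def noisy_table():
    """51 chemicals, sigma=0.3, truth = combined structural-protein coefficients."""
    return make_table(seed=12345)


@pytest.fixture
def noise_free_table():
    """Exact affine response: every fit/validation statistic is deterministic."""
    return make_table(sigma=0.0, seed=12345)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
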