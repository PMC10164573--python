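import warnings

import numpy as np
import pytest

from minicircle.elastic import ElasticParams, MinimizerConfig, minimize_shape

# elastic benchmark geometries: steric thickness 20 Å at the published
# aspect ratios d_s/L
L_336 = 20.0 / 0.018
L_672 = 20.0 / 0.0090


@pytest.fixture(scope="session")
def params_336():
    return ElasticParams(contour_length_L=L_336)


@pytest.fixture(scope="session")
def params_672():
    return ElasticParams(contour_length_L=L_672)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-budget search configuration for test-suite minimisations."""
    return MinimizerConfig(mc_steps=2500, quench_maxfev=2000, rng_seed=7)


@pytest.fixture(scope="session")
def writhed_shape_336(params_336, fast_config):
    """One minimised deeply supercoiled shape (ΔLk = −3.2), shared by tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return minimize_shape(-3.2, params_336, fast_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
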