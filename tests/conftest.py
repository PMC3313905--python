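import numpy as np
import pytest

from gcmarray.synthetic import SimulationConfig, generate_loop_experiment


@pytest.fixture(scope="session")
def noiseless_loop():
    """Loop slides with no noise, no dye bias, no outliers: the
    multiplicative background model is exactly invertible."""
    cfg = SimulationConfig(
        n_features=200,
        background_noise_sd=0.0,
        dye_bias_coefficients=(0.0, 0.0, 0.0),
        outlier_fraction=0.0,
        de_fraction=0.1,
        seed=3,
    )
    return cfg, generate_loop_experiment(cfg)


@pytest.fixture(scope="session")
def noisy_loop():
    cfg = SimulationConfig(n_features=500, seed=5)
    return cfg, generate_loop_experiment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
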