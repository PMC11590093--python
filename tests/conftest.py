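import numpy as np
import pytest

from adhekin.synthetic import (
    KineticParams,
    SyntheticConfig,
    generate_experiment,
)


@pytest.fixture(scope="session")
def noiseless_config():
    return SyntheticConfig(
        n_wells=2,
        n_cells_per_well=8,
        noise_sigma=0.0,
        cell_types={
            "fast": KineticParams(amplitude_pm=150.0, rate_per_min=0.1, onset_jitter_min=0.0),
            "slow": KineticParams(amplitude_pm=220.0, rate_per_min=0.05, onset_jitter_min=0.0),
        },
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_experiment(noiseless_config):
    return generate_experiment(noiseless_config)


@pytest.fixture(scope="session")
def noisy_experiment():
    cfg = SyntheticConfig(n_wells=3, n_cells_per_well=6, noise_sigma=5.0, seed=3)
    return generate_experiment(cfg)
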