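import warnings

import numpy as np
import pytest

import kiwispec as ks
from kiwispec.synthetic import SimulationConfig, simulate_samples

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def grid():
    return ks.default_grid()


@pytest.fixture(scope="session")
def campaign(grid):
    """The full emulated campaign: 4 stages x 50 fruit, default config."""
    return simulate_samples(SimulationConfig(seed=0), grid)


@pytest.fixture(scope="session")
def small_campaign(grid):
    """A cheap 4 x 5 campaign for unit-level tests."""
    return simulate_samples(SimulationConfig(n_per_stage=5, seed=11), grid)


@pytest.fixture(scope="session")
def split140(campaign):
    spectra, reference, _ = campaign
    return ks.spxy_split(spectra, reference, n_cal=140)


@pytest.fixture(scope="session")
def snv_campaign(campaign):
    spectra, _, _ = campaign
    return ks.snv_table(spectra)


@pytest.fixture(scope="session")
def noiseless_config():
    """Generator config with every stochastic disturbance switched off."""
    return SimulationConfig(n_per_stage=5, seed=5, noise_sd=0.0,
                            continuum_sd=0.0, gain_range=(1.0, 1.0),
                            offset_range=(0.0, 0.0),
                            index_noise_sd=(0.0,) * 5)
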