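import numpy as np
import pytest

from dceleak import (
    AcquisitionParams,
    FitConfig,
    SimulationConfig,
    TissueParams,
    simulate_clean_pair,
)


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def nawm() -> TissueParams:
    """NAWM-like reference tissue: Fp 10 ml/100g/min, PS 3e-4, vp 0.006, ve 0.2."""
    return TissueParams()


@pytest.fixture(scope="session")
def sim_cfg() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def clean_pair(sim_cfg):
    """Noise-free (VIF, tissue) coarse pair under the reference conditions."""
    return simulate_clean_pair(sim_cfg)


@pytest.fixture()
def fit_cfg() -> FitConfig:
    return FitConfig(seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
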