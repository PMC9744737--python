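import numpy as np
import pytest

from csfseverity.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One training-like synthetic cohort shared across read-only tests."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def quiet_cohort():
    """Near-noiseless cohort: planted effects recoverable to tight tolerance."""
    cfg = SimulationConfig(seed=5, resid_sd=1e-9, module_resid_sd=1e-9,
                           severity_noise_sd=1e-9, bpfr_noise_sd=0.0,
                           deficit_sd=0.0)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
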