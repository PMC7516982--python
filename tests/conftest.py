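import numpy as np
import pytest

from oepiv import OEPIVParams, ResidualStudyConfig
from oepiv.simstudy import calibrate_censoring_rho, generate_regression_sample

SET_I = OEPIVParams(lam=0.3, a=0.4, theta=0.5, alpha=0.2)
SET_II = OEPIVParams(lam=0.2, a=0.1, theta=0.6, alpha=0.15)
EXP1 = OEPIVParams(1.0, 1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def set_i():
    return SET_I


@pytest.fixture(scope="session")
def set_ii():
    return SET_II


@pytest.fixture(scope="session")
def exp1():
    return EXP1


@pytest.fixture(scope="session")
def random_valid_params():
    """20+ random valid parameter vectors spanning moderate shapes."""
    rng = np.random.default_rng(2024)
    out = []
    for _ in range(22):
        out.append(OEPIVParams(*np.exp(rng.uniform(-1.2, 1.2, size=4))))
    return out


@pytest.fixture(scope="session")
def regression_sample_mid():
    """A censored-regression sample from the canonical design, n=150/10%."""
    cfg = ResidualStudyConfig(n=150, censor_level=0.1, seed=7)
    rho = calibrate_censoring_rho(cfg, 0.1, seed=8)
    rng = np.random.default_rng(9)
    return generate_regression_sample(cfg, rho, rng), cfg
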