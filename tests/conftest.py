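import numpy as np
import pytest
from hypothesis import settings

from accelerage import GompertzParams, SimConfig, WeibullParams, draw_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# canonical adult-mortality parameters used across the suite
GOMPERTZ = GompertzParams(a=float(np.exp(-9.0)), b=0.085)
WEIBULL = WeibullParams(lam=34.0**-10, nu=8.0)


@pytest.fixture(scope="session")
def gompertz():
    return GOMPERTZ


@pytest.fixture(scope="session")
def weibull():
    return WEIBULL


@pytest.fixture(scope="session")
def aft_cohort():
    """Medium Gompertz-AFT cohort reused by read-only tests."""
    return draw_cohort(SimConfig(mechanism="gompertz_aft", n_obs=4000, seed=101))


@pytest.fixture(scope="session")
def ph_cohort():
    return draw_cohort(SimConfig(mechanism="gompertz_ph", n_obs=4000, seed=102))
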