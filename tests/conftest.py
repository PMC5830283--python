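import logging

import numpy as np
import pytest
from hypothesis import settings

import patternirt as pt

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

logging.getLogger("patternirt").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bank():
    """The packaged two-factor calibration of the 9-item scale (probit)."""
    return pt.reference_bank()


@pytest.fixture(scope="session")
def logistic_bank():
    return pt.reference_bank(link="logistic")


@pytest.fixture(scope="session")
def study(bank):
    """One simulated study population at the default conditions
    (n = 344, latent correlation 0.5)."""
    return pt.simulate_dataset(pt.SimulationConfig(n_respondents=344, seed=3))


@pytest.fixture(scope="session")
def toy_1d_bank():
    """Two binary items on a single dimension, for brute-force cross-checks."""
    items = (
        pt.ItemParameters("t1", a=[1.2], d=[0.4], link="probit"),
        pt.ItemParameters("t2", a=[0.8], d=[-0.6], link="probit"),
    )
    return pt.ItemBank(items=items)


@pytest.fixture(scope="session")
def toy_2d_bank():
    """Four 3-category items, two per dimension, for quadrature oracles."""
    items = (
        pt.ItemParameters("u1", a=[1.5, 0.0], d=[0.8, -0.9], link="probit"),
        pt.ItemParameters("u2", a=[0.0, 1.1], d=[0.3, -1.2], link="probit"),
        pt.ItemParameters("u3", a=[0.9, 0.0], d=[1.0, -0.4], link="probit"),
        pt.ItemParameters("u4", a=[0.0, 1.3], d=[0.6, -0.7], link="probit"),
    )
    return pt.ItemBank(items=items)
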