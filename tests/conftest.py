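"""Shared fixtures: small simulated cohorts and fitted models, reused across
test modules to keep the suite fast."""

import dataclasses

import numpy as np
import pytest

from clpn import PanelGVAR, simulate
from clpn.cohort import null_scenario, random_sparse_scenario


@pytest.fixture(scope="session")
def sparse_scenario():
    """Random sparse 5-node ground truth used by several suites."""
    return dataclasses.replace(random_sparse_scenario(5, n_nodes=5, seed=3),
                               n_persons=400)


@pytest.fixture(scope="session")
def sparse_data(sparse_scenario):
    return simulate(sparse_scenario)


@pytest.fixture(scope="session")
def fitted(sparse_data):
    """One ML fit with standard errors, shared by model/stability tests."""
    return PanelGVAR(sparse_data).fit()


@pytest.fixture(scope="session")
def null_data_small():
    return simulate(null_scenario(300, n_nodes=4, n_waves=4, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
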