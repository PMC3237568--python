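import numpy as np
import pytest

from egfrnet import build_egfr_network
from egfrnet.dynamics import simulate
from egfrnet.experiments import sustained_scenario, transient_scenario
from egfrnet.sensitivity import sensitivity_scan


@pytest.fixture(scope="session")
def egfr_model():
    return build_egfr_network()


@pytest.fixture(scope="session")
def transient_traj(egfr_model):
    """Reference-dose transient EGF stimulation, 60 min, 0.1-min grid."""
    return simulate(egfr_model, transient_scenario())


@pytest.fixture(scope="session")
def sustained_traj(egfr_model):
    """Sustained receptor activation (EGF clamped, internalization removed)."""
    return simulate(egfr_model, sustained_scenario())


@pytest.fixture(scope="session")
def sensitivity_table(egfr_model):
    """Full 28-species x 3-readout sensitivity scan (transient scenario)."""
    return sensitivity_scan(egfr_model, transient_scenario(n_points=301))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
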