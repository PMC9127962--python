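import numpy as np
import pytest

from gcda.examples import (
    NOR_PARAMS,
    RECEIVER1_PARAMS,
    RECEIVER2_PARAMS,
    dose_response_assay,
    hill2_network,
    log_dose_series,
    oscillator_network,
    receiver_network,
    source_reporter_network,
)
from gcda.growth import ConstantGrowth
from gcda.simulation import run_assay


@pytest.fixture(scope="session")
def growth():
    return ConstantGrowth(mu0=0.5)


@pytest.fixture(scope="session")
def oscillator():
    return oscillator_network()


@pytest.fixture(scope="session")
def source_net():
    return source_reporter_network(alpha=10.0, gamma=1.0)


@pytest.fixture(scope="session")
def receiver1_doses():
    return [0.0, 0.01, 0.1, 0.3, 1.0, 3.0, 10.0, 100.0]


@pytest.fixture(scope="session")
def receiver1_table(growth, receiver1_doses):
    """Noiseless kinetic dose-response data for the first receiver device."""
    net = receiver_network("ahl1", RECEIVER1_PARAMS, gamma_reporter=1.0,
                           signal="YFP")
    assay = dose_response_assay(
        net, [{"ahl1": c} for c in receiver1_doses],
        duration=10.0, interval=0.5, growth=growth, name="rec1",
    )
    return run_assay(assay)


@pytest.fixture(scope="session")
def nor_grid_table(growth):
    """8x8 two-supplement grid driving the NOR device via both receivers."""
    net = hill2_network()
    d1 = log_dose_series(0.01, 100.0, 7)
    d2 = log_dose_series(0.02, 200.0, 7)
    doses = [{"ahl1": a, "ahl2": b} for a in d1 for b in d2]
    assay = dose_response_assay(net, doses, duration=10.0, interval=0.5,
                                growth=growth, name="nor")
    return run_assay(assay), doses
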