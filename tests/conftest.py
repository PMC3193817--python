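import numpy as np
import pytest

from p2x3kin import (
    KineticScheme,
    load_rate_set,
    simulate_paired_pulse,
    simulated_features,
)


@pytest.fixture(scope="session")
def scheme():
    return KineticScheme.default()


@pytest.fixture(scope="session")
def control_rates():
    return load_rate_set("control")


@pytest.fixture(scope="session")
def mbcd_rates():
    return load_rate_set("MbCD")


@pytest.fixture(scope="session")
def control_paired(control_rates):
    """Control paired-pulse simulation (0.01 mM, 2 s pulses, 30 s apart)."""
    return simulate_paired_pulse(control_rates, 0.01, 2.0, 30.0)


@pytest.fixture(scope="session")
def mbcd_paired(mbcd_rates):
    return simulate_paired_pulse(mbcd_rates, 0.01, 2.0, 30.0)


@pytest.fixture(scope="session")
def control_features(control_rates):
    return simulated_features(control_rates)


@pytest.fixture(scope="session")
def mbcd_features(mbcd_rates):
    return simulated_features(mbcd_rates)
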