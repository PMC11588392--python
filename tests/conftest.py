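import numpy as np
import pytest

import fetmem as fm

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def amnion():
    return fm.load_paper_parameters("table1_amnion")


@pytest.fixture(scope="session")
def chorion():
    return fm.load_paper_parameters("table2_chorion")


@pytest.fixture(scope="session")
def laminate():
    return fm.load_paper_parameters("table3_laminate")


@pytest.fixture(scope="session")
def trilayer_run(laminate):
    """One shared trilayer bulge simulation: pre-inflation at 0.2 kPa, ramp
    toward 20 kPa, stopping early if the flat-referenced apex displacement
    reaches 7.8 mm (the end-of-test state)."""
    proto = fm.make_protocol("simulation", step_kpa=0.2)
    return fm.inflate(laminate, proto, n_nodes=150, stop_at_displacement=7.8,
                      displacement_reference="flat")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231228)
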