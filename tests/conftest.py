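import pytest

from isomix import (
    constant_sources,
    diet_switch_schedule,
    make_turnover,
)


@pytest.fixture(scope="session")
def constant_pool():
    """Flat sources at 0 and 10 permil, discrimination 1 permil each."""
    return constant_sources((0.0, 10.0), (1.0, 1.0), 500.0)


@pytest.fixture(scope="session")
def single_switch():
    return diet_switch_schedule(0.002, 500.0)


@pytest.fixture(scope="session")
def four_switch():
    return diet_switch_schedule(0.008, 500.0)


@pytest.fixture(scope="session")
def lam_intermediate():
    return make_turnover("constant", lambda0=0.02)
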