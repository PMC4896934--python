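import pytest
from hypothesis import settings

import cardioresp as cr

settings.register_profile("deterministic", derandomize=True, max_examples=60)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def healthy():
    return cr.load_profile("healthy")


@pytest.fixture(scope="session")
def hf():
    return cr.load_profile("hf")


@pytest.fixture(scope="session")
def healthy_graded(healthy):
    """Full graded-exercise run, healthy condition (shared across tests)."""
    num = cr.NumericalSettings()
    return cr.simulate(healthy, cr.graded_protocol(num.stage_duration), num)


@pytest.fixture(scope="session")
def hf_graded(hf):
    num = cr.NumericalSettings()
    return cr.simulate(hf, cr.graded_protocol(num.stage_duration), num)


@pytest.fixture(scope="session")
def healthy_summaries(healthy_graded):
    return cr.steady_state_summary(healthy_graded)


@pytest.fixture(scope="session")
def hf_summaries(hf_graded):
    return cr.steady_state_summary(hf_graded)
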