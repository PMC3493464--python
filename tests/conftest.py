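import warnings

import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

from lignindesign import (
    Design,
    base_scaffold,
    default_scenario_set,
    enumerate_configurations,
)


@pytest.fixture(scope="session")
def scaffold():
    return base_scaffold()


@pytest.fixture(scope="session")
def configs():
    return enumerate_configurations()


@pytest.fixture(scope="session")
def by_label(configs):
    return {c.label: c for c in configs}


@pytest.fixture(scope="session")
def scenario_set():
    return default_scenario_set()


@pytest.fixture(scope="session")
def design_a_m2m5(by_label):
    return Design(by_label["A"], frozenset({"M2", "M5"}))
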