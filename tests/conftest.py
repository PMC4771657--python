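from datetime import date

import pytest
from hypothesis import settings

from glycalc import KineticParams, MonthlyProfile, get_scheme

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def default_scheme():
    return get_scheme("default3")


@pytest.fixture
def params():
    return KineticParams()


@pytest.fixture
def issc():
    return MonthlyProfile((180, 170, 160))


@pytest.fixture
def iic():
    return MonthlyProfile((250, 160, 100))


@pytest.fixture
def ind():
    return MonthlyProfile((100, 100, 310))


@pytest.fixture
def test_date():
    return date(2016, 2, 29)
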