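import pytest
from hypothesis import HealthCheck, settings

from nutrimendel import datasets

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def country_records():
    return datasets.country_table()


@pytest.fixture(scope="session")
def instruments_by_pufa():
    return datasets.pufa_instruments()


@pytest.fixture(scope="session")
def scz_outcome():
    return datasets.schizophrenia_outcome()
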