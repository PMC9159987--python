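import pytest

from reticulator.io import load_fixture
from reticulator.parentage import infer_all, records_from_fixture


@pytest.fixture(scope="session")
def fixture_data():
    return load_fixture()


@pytest.fixture(scope="session")
def fixture_records(fixture_data):
    return records_from_fixture(fixture_data)


@pytest.fixture(scope="session")
def fixture_inference(fixture_records):
    """(statuses, matrix, maternal, registry, formulas) on the fixture."""
    return infer_all(fixture_records)
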