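import pytest

from mttrnascreen import default_catalog
from mttrnascreen.io import load_study_table


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def study_table():
    return load_study_table()
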