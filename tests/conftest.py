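import pytest

from agphot.descriptors import load_table1_fixtures


@pytest.fixture(scope="session")
def table1():
    """The four packaged benchmark emitters, in fixed order."""
    return load_table1_fixtures()


@pytest.fixture(scope="session")
def table1_by_name(table1):
    return {d.name: d for d in table1}
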