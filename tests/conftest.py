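import pytest

from compord import table1_fixtures


@pytest.fixture(scope="session")
def table1():
    """The six bundled example proteins, keyed by id."""
    return {rec.id: rec for rec in table1_fixtures()}
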