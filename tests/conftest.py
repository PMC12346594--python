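import pytest

from enantiosep.dataio import load_table1


@pytest.fixture(scope="session")
def table1():
    """The packaged 7 CSP x 4 eluent x 3 analyte screening table."""
    return load_table1()
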