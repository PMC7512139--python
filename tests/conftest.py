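import pytest

from netpat import build_descriptor_table, enumerate_patterns


@pytest.fixture(scope="session")
def catalog2():
    return enumerate_patterns(2)


@pytest.fixture(scope="session")
def catalog3():
    return enumerate_patterns(3)


@pytest.fixture(scope="session")
def catalog4():
    return enumerate_patterns(4)


@pytest.fixture(scope="session")
def table3(catalog3):
    return build_descriptor_table(catalog3)
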