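import pytest

from parpsense import load_fixture


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3")


@pytest.fixture(scope="session")
def table5():
    return load_fixture("table5")
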