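import pytest

from kpuu import TranswellGeometry, load_pooled, load_table2, load_table3


@pytest.fixture(scope="session")
def geom():
    return TranswellGeometry(V_lum=1500.0, V_ab=2500.0, A=4.7)


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def table3():
    return load_table3()


@pytest.fixture(scope="session")
def pooled():
    return load_pooled()
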