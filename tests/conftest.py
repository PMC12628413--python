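import warnings

import pytest

import dustgeorisk as dg

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def table():
    """The packaged 24-sample study dataset."""
    return dg.fixture_table()


@pytest.fixture(scope="session")
def cf(table):
    return dg.contamination_factor(table)


@pytest.fixture(scope="session")
def X_logz(table):
    X, _ = dg.preprocess(table)
    return X


@pytest.fixture(scope="session")
def X_rawz(table):
    X, _ = dg.preprocess(table, log=False)
    return X
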