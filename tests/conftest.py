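import pytest

from clusterline import (
    load_ddh_panel,
    load_qnm_reference,
    load_tp_a0316,
    load_tp_a0468,
)


@pytest.fixture(scope="session")
def tp_a0316():
    return load_tp_a0316()


@pytest.fixture(scope="session")
def tp_a0468():
    return load_tp_a0468()


@pytest.fixture(scope="session")
def qnm():
    return load_qnm_reference()


@pytest.fixture(scope="session")
def ddh_panel():
    return load_ddh_panel()
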