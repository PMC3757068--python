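import pytest

from fluximba.fixtures import make_fixture


@pytest.fixture
def figure1():
    return make_fixture("figure1")


@pytest.fixture
def figure1_model(figure1):
    return figure1[0]


@pytest.fixture
def degenerate():
    return make_fixture("degenerate")


@pytest.fixture
def nitrogen():
    return make_fixture("nitrogen_assimilation")
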