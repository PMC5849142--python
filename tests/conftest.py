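import pytest

from heparlib import get_fixture

C14_SEQ = ("GlcNS6S(1-4)GlcA(1-4)GlcNS3S6S(1-4)IdoA2S(1-4)GlcNS6S(1-4)"
           "GlcA-pNA-N3")


@pytest.fixture
def seed():
    return get_fixture("seed").oligo


@pytest.fixture
def c14():
    return get_fixture("14").oligo


@pytest.fixture
def inter_iv():
    return get_fixture("IV").oligo


@pytest.fixture
def inter_vi():
    return get_fixture("VI").oligo
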