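import pytest

from cliwrap import lower, optimize
from cliwrap.fixtures import fixture_descriptor


@pytest.fixture(scope="session")
def toycalc():
    return fixture_descriptor("toycalc")


@pytest.fixture(scope="session")
def toycalc_ir(toycalc):
    return optimize(lower(toycalc))


@pytest.fixture(scope="session")
def bet_ir():
    return optimize(lower(fixture_descriptor("bet_like")))


@pytest.fixture(scope="session")
def minimal_ir():
    return optimize(lower(fixture_descriptor("minimal")))
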