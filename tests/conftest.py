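import pytest

from translerr import GenotypeFitnessView, make_fixture
from translerr.condition import PopulationParams


@pytest.fixture(scope="session")
def enumerable():
    """(landscape, table, code, view) of the seeded rugged L=2 fixture."""
    landscape, table, code = make_fixture("enumerable-L2")
    return landscape, table, code, GenotypeFitnessView(landscape)


@pytest.fixture(scope="session")
def flat():
    landscape, table, code = make_fixture("flat")
    return landscape, table, code, GenotypeFitnessView(landscape)


@pytest.fixture(scope="session")
def two_peak():
    landscape, table, code = make_fixture("two-peak")
    return landscape, table, code, GenotypeFitnessView(landscape)


@pytest.fixture(scope="session")
def toy_ad():
    landscape, table, code = make_fixture("toy-AD")
    return landscape, table, code, GenotypeFitnessView(landscape)


@pytest.fixture
def params_1e6():
    return PopulationParams(N=10**6, n=1)
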