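import pytest
from hypothesis import settings

from endocea import base_case_parameters

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from endocea.cohort import Strategy, run_cohort
from endocea.synthetic import make_population


@pytest.fixture(scope="session")
def base():
    """(ModelParameters, CostParameters, distributions) base case."""
    return base_case_parameters()


@pytest.fixture(scope="session")
def mp(base):
    return base[0]


@pytest.fixture(scope="session")
def cp(base):
    return base[1]


@pytest.fixture(scope="session")
def dists(base):
    return base[2]


@pytest.fixture(scope="session")
def pop():
    return make_population()


@pytest.fixture(scope="session")
def trace_sc(mp):
    return run_cohort(mp, Strategy.SELF_CARE)


@pytest.fixture(scope="session")
def trace_int(mp):
    return run_cohort(mp, Strategy.INTERVENTION)
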