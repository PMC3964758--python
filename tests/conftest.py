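import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from exergen import Individual, Pedigree


@pytest.fixture
def mz_pair_pedigree() -> Pedigree:
    """One family: founder parents and an MZ twin pair."""
    return Pedigree([
        Individual("F", "fam1", sex="male", in_analysis=False),
        Individual("M", "fam1", sex="female", in_analysis=False),
        Individual("T1", "fam1", "F", "M", sex="female", zygosity="MZ", age=30.0),
        Individual("T2", "fam1", "F", "M", sex="female", zygosity="MZ", age=30.0),
    ])


@pytest.fixture
def nuclear_pedigree() -> Pedigree:
    """Parents (in the analysis sample) plus a DZ pair and a sibling."""
    return Pedigree([
        Individual("F", "fam1", sex="male", age=49.0),
        Individual("M", "fam1", sex="female", age=47.0),
        Individual("T1", "fam1", "F", "M", sex="male", zygosity="DZ", age=20.0),
        Individual("T2", "fam1", "F", "M", sex="female", zygosity="DZ", age=20.0),
        Individual("S1", "fam1", "F", "M", sex="female", age=24.0),
    ])


@pytest.fixture
def three_generation_pedigree() -> Pedigree:
    """Grandparents, parents, grandchild: exercises recursive kinship."""
    return Pedigree([
        Individual("GF", "fam1", sex="male", age=50.0),
        Individual("GM", "fam1", sex="female", age=50.0),
        Individual("P1", "fam1", "GF", "GM", sex="female", age=45.0),
        Individual("P2", "fam1", "GF", "GM", sex="male", age=43.0),
        Individual("SP", "fam1", sex="male", age=46.0),
        Individual("C1", "fam1", "SP", "P1", sex="female", age=20.0),
    ])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
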