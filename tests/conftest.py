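import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cupep.core import AMINO_ACIDS, Peptide, PeptidePopulation

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20250922)


def random_sequence(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture
def random_peptides(rng):
    """1000 random peptides, lengths 5-30."""
    return [random_sequence(rng, int(rng.integers(5, 31))) for _ in range(1000)]


@pytest.fixture
def two_condition_population():
    """Small hand-built population with both digestion conditions."""
    peps = [
        Peptide("HWPLPPFAK", condition="pep_tryp", fraction="E", probability=1.0),
        Peptide("RHASEGGHG", condition="pep_tryp", fraction="E", probability=0.995),
        Peptide("GHWPLPPFV", condition="papain", fraction="E", probability=0.99),
        Peptide("VASEGGPLI", condition="papain", fraction="E", probability=1.0),
    ]
    return PeptidePopulation(peps, "toy")
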