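import numpy as np
import pytest

from alukit import build_signature_set
from alukit.fixtures import random_genome

_BASES = "ACGT"


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def sigs():
    return build_signature_set()


@pytest.fixture(scope="session")
def toy_genome():
    """5 kb deterministic random genome shared across unit tests."""
    return random_genome(101, length=5_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
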