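import numpy as np
import pytest
from hypothesis import settings

from badass import ReferenceSequence, make_additive_landscape, make_epistatic_landscape

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_reference(length: int, seed: int, id: str = "ref") -> ReferenceSequence:
    rng = np.random.default_rng(seed)
    return ReferenceSequence("".join(rng.choice(list(AA), size=length)), id=id)


@pytest.fixture(scope="session")
def ref5() -> ReferenceSequence:
    return ReferenceSequence("ACDEF", id="ref5")


@pytest.fixture(scope="session")
def ref6() -> ReferenceSequence:
    return ReferenceSequence("ACDEFG", id="ref6")


@pytest.fixture(scope="session")
def ref30() -> ReferenceSequence:
    return random_reference(30, seed=42, id="ref30")


@pytest.fixture(scope="session")
def additive5(ref5):
    return make_additive_landscape(ref5, seed=1)


@pytest.fixture(scope="session")
def epistatic5(ref5):
    return make_epistatic_landscape(ref5, seed=1)


@pytest.fixture(scope="session")
def epistatic6(ref6):
    return make_epistatic_landscape(ref6, seed=1)
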