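import numpy as np
import pytest

from ribodesign import NucleotideSequence, ObjectiveConfig, ReferenceEnergyModel

ALPHABET = "ACGU"


@pytest.fixture(scope="session")
def model():
    return ReferenceEnergyModel()


@pytest.fixture(scope="session")
def obj_cfg():
    return ObjectiveConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_seq(rng, length, name="s"):
    return NucleotideSequence(
        name, "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))
    )
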