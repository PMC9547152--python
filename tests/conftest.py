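import numpy as np
import pytest

from snoguard.fixtures import (
    load_cleavage_profiles,
    load_snorna_reference,
    load_trna_reference,
)


@pytest.fixture(scope="session")
def trna():
    return load_trna_reference()


@pytest.fixture(scope="session")
def sno():
    return load_snorna_reference()


@pytest.fixture(scope="session")
def profiles():
    return load_cleavage_profiles()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_rna(rng, length, alphabet="ACGU"):
    return "".join(rng.choice(list(alphabet), size=length))
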