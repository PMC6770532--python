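import numpy as np
import pytest

from lncstack.hexamer import HexamerTable
from lncstack.assemble import feature_schema


@pytest.fixture(scope="session")
def neutral_table():
    return HexamerTable.neutral()


@pytest.fixture(scope="session")
def schema():
    return feature_schema()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
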