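import random

import pytest
from hypothesis import settings

from mtmisalign.genome import MtGenome
from mtmisalign.thermo import load_nn_parameters

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return load_nn_parameters()


@pytest.fixture(scope="session")
def random_genome():
    """A 3-kb i.i.d. circular genome, fixed seed."""
    rng = random.Random(20240901)
    return MtGenome("toy3k", "".join(rng.choice("ACGT") for _ in range(3000)))
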