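import numpy as np
import pytest

from intron_atlas.folding import BaselineEngine


@pytest.fixture(scope="session")
def engine():
    return BaselineEngine()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rna(rng, n: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=n)])
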