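import numpy as np
import pytest

from hijackscan import synthetic


@pytest.fixture(scope="session")
def locus():
    return synthetic.generate_locus(seed=1)


@pytest.fixture(scope="session")
def small_lengths():
    return {"chr4s": 10_000, "chr9s": 8_000}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
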