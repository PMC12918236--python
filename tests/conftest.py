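import numpy as np
import pytest

from omlo import codec


@pytest.fixture(scope="session")
def mhd4_words():
    return codec.build_codebook(16, 4, 4)


@pytest.fixture(scope="session")
def codebook(mhd4_words):
    genes = [f"G{i}" for i in range(1, 137)]
    return codec.assign_barcodes(mhd4_words, genes, n_blanks=4, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
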