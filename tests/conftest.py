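import numpy as np
import pytest

from exmpipe import synthetic


@pytest.fixture(scope="session")
def codebook():
    return synthetic.default_codebook()


@pytest.fixture(scope="session")
def cell_field():
    """Small field of 10 nuclei reused across detection tests."""
    return synthetic.gen_cell_images(10, 256, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
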