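import numpy as np
import pytest

from mdcompare.synthetic import GeneratorSpec, gen_toy_complex


@pytest.fixture(scope="session")
def toy_complex():
    """Two-chain toy backbone complex: (topology, base coordinates)."""
    return gen_toy_complex(GeneratorSpec(seed=0, n_frames=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
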