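import numpy as np
import pytest

from hyperspot import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_ds():
    """60-spot, 30-gene, 3-domain layered fixture (fast paths)."""
    return generate(
        SyntheticSpec(n_spots=60, n_genes=30, n_domains=3, markers_per_domain=3, seed=7)
    )


@pytest.fixture
def default_ds():
    """The default study fixture: 800 spots, 200 genes, 4 layered domains."""
    return generate(SyntheticSpec(seed=12345))
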