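import numpy as np
import pytest

from dynfc.connectomes import StructuralConnectome
from dynfc.synthetic import generate_connectome


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_connectome(n: int, seed: int = 0, density: float = 0.6) -> StructuralConnectome:
    """Small dense random connectome for unit tests (not the generator)."""
    rng = np.random.default_rng(seed)
    w = rng.random((n, n))
    w[rng.random((n, n)) > density] = 0.0
    w = np.triu(w, k=1)
    w = w + w.T
    l = 10.0 + 90.0 * rng.random((n, n))
    l = np.triu(l, k=1)
    l = l + l.T
    l[w == 0] = 0.0
    return StructuralConnectome(weights=w, lengths=l)


@pytest.fixture(scope="session")
def sc8():
    return generate_connectome(n_regions=8, density=0.5, seed=3)


@pytest.fixture(scope="session")
def sc15():
    return generate_connectome(n_regions=15, density=0.35, seed=42)
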