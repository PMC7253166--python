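import numpy as np
import pytest


def random_stable(n: int, seed: int, margin: float = 0.5, symmetric: bool = False):
    """Random stable state matrix with spectral abscissa <= -margin."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, n))
    if symmetric:
        A = 0.5 * (A + A.T)
        shift = np.max(np.linalg.eigvalsh(A))
    else:
        shift = np.max(np.real(np.linalg.eigvals(A)))
    return A - (shift + margin) * np.eye(n)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
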