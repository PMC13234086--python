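import numpy as np
import pytest

from cotula.params import StaticParams


def random_static_params(rng, N=5, M=4, K=2, coupling_scale=0.3):
    """A well-conditioned random static model."""
    return StaticParams(
        a=coupling_scale * rng.standard_normal(N),
        b=rng.standard_normal(M),
        B_not=rng.standard_normal((M, N)),
        l=0.5 * rng.standard_normal(K),
        L_not=0.5 * rng.standard_normal((K, N)),
        psi=rng.uniform(0.5, 1.5),
        Psi_not=rng.uniform(0.5, 1.5, N),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def static_params(rng):
    return random_static_params(rng)
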