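import numpy as np
import pytest

from delaylump import ChainSpecParams, random_chain


@pytest.fixture
def chain3():
    """n=3 chain with c_f=1 (S2->S3) and c_b=2 (S2->S1)."""
    return random_chain(ChainSpecParams(n=3, forward=[1.0, 1.0], backward=[2.0, 2.0]))


@pytest.fixture
def chain4_symmetric():
    """n=4 chain with all rates 1."""
    return random_chain(ChainSpecParams(n=4, forward=[1.0] * 3, backward=[1.0] * 3))


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)


def retry_stochastic(check, seeds=(101, 202)):
    """Run a seeded stochastic check; retry once with a fresh documented seed
    on failure (a second failure is a real failure)."""
    last = None
    for s in seeds:
        try:
            check(s)
            return
        except AssertionError as exc:
            last = exc
    raise last
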