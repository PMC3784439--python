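import numpy as np
import pytest

from rvtrio.io import TrioCohort


def random_mendelian_cohort(rng: np.random.Generator, n: int, L: int, q: float = 0.2) -> TrioCohort:
    """Random HWE parents with a properly transmitted child (no ascertainment)."""
    father = rng.binomial(2, q, size=(n, L))
    mother = rng.binomial(2, q, size=(n, L))

    def transmit(g):
        out = (g == 2).astype(np.int64)
        het = g == 1
        out[het] = rng.integers(0, 2, size=int(het.sum()))
        return out

    child = transmit(father) + transmit(mother)
    return TrioCohort(father, mother, child, [f"v{j}" for j in range(L)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_cohort(rng):
    return random_mendelian_cohort(rng, n=40, L=3)
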