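import numpy as np
import pytest

import noiasim as ns


@pytest.fixture(scope="session")
def small_genome():
    return ns.build_genome(2, 1.0, 25, rng_seed=101)


@pytest.fixture(scope="session")
def founder_pop(small_genome):
    """Small fast-founder population used across unit tests."""
    return ns.sample_founders_fast(small_genome, n_males=40, n_females=200,
                                   rng_seed=202)


@pytest.fixture(scope="session")
def small_pop_fixture():
    return ns.make_fixture("small_pop")


def hwe(p: float) -> np.ndarray:
    return np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])


@pytest.fixture
def hwe_freqs():
    return hwe


def wls_partition_oracle(W9, freq9, c9):
    """Independent weighted-least-squares oracle: solve
    argmin_b sum_g f_g (c_g - (W b)_g)^2 via lstsq on sqrt-weighted rows."""
    sw = np.sqrt(freq9)
    b, *_ = np.linalg.lstsq(W9 * sw[:, None], c9 * sw, rcond=None)
    return b
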