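import numpy as np
import pytest

from unicyc import build_rate_set, load_enzyme


@pytest.fixture(scope="session")
def tpi():
    return load_enzyme("tpi")


@pytest.fixture(scope="session")
def tpi_rates(tpi):
    return build_rate_set(tpi)


def random_rate_set(rng: np.random.Generator, n_states: int):
    """Log-uniform random positive rate set spanning realistic magnitudes."""
    from unicyc import RateSet

    k = 10 ** rng.uniform(-2, 8, size=2 * n_states)
    return RateSet(k=k, n_states=n_states)
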