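import numpy as np
import pytest

from eqmotif.solvers import equilibrium_oracle


RATE_LO, RATE_HI = 1e-2, 1e2


def draw_rates(rng, k):
    """Log-uniform rate draws in [1e-2, 1e2]."""
    return np.exp(rng.uniform(np.log(RATE_LO), np.log(RATE_HI), size=k))


def oracle_of(motif_result):
    """Nullspace equilibrium of a motif's explicit model."""
    return equilibrium_oracle(motif_result.oracle_rate_matrix())


@pytest.fixture
def rng():
    return np.random.default_rng(20140054)
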