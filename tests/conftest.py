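import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def kcv_scheme():
    from poreblock.ionflux import kcv_like_scheme

    return kcv_like_scheme()


@pytest.fixture(scope="session")
def symmetric_cond():
    from poreblock.ionflux import symmetric_kcl_conditions

    return symmetric_kcl_conditions()


@pytest.fixture(scope="session")
def blocked_scheme(kcv_scheme):
    from poreblock.ionflux import apply_block

    return apply_block(kcv_scheme)


def random_irreducible_scheme(rng: np.random.Generator, n_states: int):
    """Random irreducible generator matrix: a ring plus random extra edges,
    rates log-uniform in [1, 100] s^-1."""
    Q = np.zeros((n_states, n_states))
    def rate():
        return float(10 ** rng.uniform(0, 2))
    for i in range(n_states):
        j = (i + 1) % n_states
        Q[i, j] = rate()
        Q[j, i] = rate()
    n_extra = rng.integers(0, n_states + 1)
    for _ in range(n_extra):
        i, j = rng.integers(0, n_states, 2)
        if i != j:
            Q[i, j] += rate()
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q
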