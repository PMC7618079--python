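import numpy as np
import pytest

from deathclock.config import expand_dimensionless
from deathclock.wellmixed import SimConfig, run_wellmixed


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def wellmixed_homotypic(beta, eta, n0=200, end_time=25.0, seed=0,
                        max_population=10_000, init="staggered"):
    """One homotypic well-mixed run at dimensionless (beta, eta), t_G = 1."""
    params = expand_dimensionless(beta, eta, t_g=1.0)
    cfg = SimConfig(
        end_time=end_time,
        initial_counts={"A": n0},
        params={"A": params},
        seed=seed,
        max_population=max_population,
        init=init,
        log_g1_exits=False,
    )
    return run_wellmixed(cfg)


def wellmixed_heterotypic(type_a, type_b, n0=100, end_time=30.0, seed=0,
                          max_population=30_000, init="staggered"):
    """One heterotypic well-mixed run for two dimensionless (beta, eta) pairs."""
    params = {
        "A": expand_dimensionless(*type_a, t_g=1.0),
        "B": expand_dimensionless(*type_b, t_g=1.0),
    }
    cfg = SimConfig(
        end_time=end_time,
        initial_counts={"A": n0, "B": n0},
        params=params,
        seed=seed,
        max_population=max_population,
        init=init,
        log_g1_exits=False,
    )
    return run_wellmixed(cfg)
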