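import numpy as np
import pytest

import dwirepeat as dr

# Chain schedule used throughout the tests: retains the same 10,000 draws as
# the package default (60000/10000/5) with less burn-in wall time.
FAST_CHAIN = dict(n_iterations=12_000, burn_in=2_000, thin=1)

#: Ground truth of the large-cohort recovery fixture.
RECOVERY_TRUTH = dict(mu=1.0, sigma_a=0.2, sigma_ab=0.05, sigma_eps_1=0.02, sigma_eps_2=0.02)
RECOVERY_ICC_INTER = 0.2**2 / (0.2**2 + 0.05**2)  # 0.941


@pytest.fixture(scope="session")
def recovery_table():
    """P=100 table simulated from known variance components."""
    spec = dr.SimulationSpec(
        P=100, mu=1.0, sigma_a=0.2, sigma_ab=0.05,
        sigma_eps_1=0.02, sigma_eps_2=0.02, seed=2, metric="median_gadc",
    )
    return dr.simulate_table(spec)


@pytest.fixture(scope="session")
def recovery_chain(recovery_table):
    cfg = dr.ChainConfig(seed=1, **FAST_CHAIN)
    return dr.run_chain(recovery_table, config=cfg)


@pytest.fixture(scope="session")
def oracle_table():
    """P=200 low-noise table for classical-vs-Bayesian oracle comparisons."""
    spec = dr.SimulationSpec(
        P=200, mu=1.0, sigma_a=0.2, sigma_ab=0.05,
        sigma_eps_1=0.02, sigma_eps_2=0.02, seed=11, metric="median_gadc",
    )
    return dr.simulate_table(spec)


@pytest.fixture(scope="session")
def oracle_chain(oracle_table):
    cfg = dr.ChainConfig(seed=3, **FAST_CHAIN)
    return dr.run_chain(oracle_table, config=cfg)
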