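"""Shared fixtures.

The two worked examples and the scaled simulations are expensive
(n = 100,000 samples, many graphical-lasso paths), so they are computed once
per session and shared between the unit tests and the acceptance tests.
Seeds are fixed for reproducibility.
"""

import numpy as np
import pytest
from hypothesis import settings

from netload import experiments

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def table1_run():
    """Mixed-sign worked example (2 factors x 6 variables, n = 100,000)."""
    return experiments.table1_example(seed=11)


@pytest.fixture(scope="session")
def table2_run():
    """Cross-loading worked example (3 + 9 variables, n = 100,000)."""
    return experiments.table2_example(seed=12)


@pytest.fixture(scope="session")
def small_sim_run():
    """Community-size dependence simulation at 25 replicates."""
    return experiments.small_simulation(seed=1, replicates=25)


@pytest.fixture(scope="session")
def contrast_run():
    """Scaled slice of the factorial design contrasting sign patterns.

    2 factors x {3, 6, 12} variables per factor x loadings 0.55 x factor
    correlation 0.30 x n = 1000, both sign patterns, 20 replicates.
    """
    conditions = experiments.main_design(
        n_factors=(2,),
        variables_per_factor=(3, 6, 12),
        loading_levels=(0.55,),
        sign_patterns=("all_positive", "half_negative"),
        factor_correlations=(0.30,),
        sample_sizes=(1000,),
    )
    return experiments.run_design(conditions, replicates=20, seed=2)


@pytest.fixture
def two_block_weights():
    """Hand-made 6-node network: two 3-node communities, weak bridge."""
    w = np.zeros((6, 6))
    w[0, 1] = w[1, 0] = 0.30
    w[0, 2] = w[2, 0] = 0.25
    w[1, 2] = w[2, 1] = 0.20
    w[3, 4] = w[4, 3] = 0.35
    w[3, 5] = w[5, 3] = 0.15
    w[4, 5] = w[5, 4] = 0.28
    w[2, 3] = w[3, 2] = 0.05
    return w


@pytest.fixture
def two_block_membership():
    return np.array([1, 1, 1, 2, 2, 2])
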