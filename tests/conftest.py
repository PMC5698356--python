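import numpy as np
import pytest

from sporeclock.synthetic import PlantedTruth, make_go_universe, simulate_expression


@pytest.fixture(scope="session")
def small_universe():
    """10 GO terms x 20 loci, no multi-membership, fixed seed."""
    return make_go_universe(n_terms=10, loci_per_term=20, multi_membership_prob=0.0, seed=7)


@pytest.fixture(scope="session")
def planted_matrix(small_universe):
    """Matrix with planted directional and temporal effects, mild noise."""
    truth = PlantedTruth(
        directional_effects={"GO:0000": 0.015, "GO:0001": -0.015},
        temporal_slopes={"GO:0002": 0.004, "GO:0003": -0.004},
        fold_change_multipliers={"bg_00010": 4.0},
        noise_sd=0.005,
        seed=11,
    )
    m = simulate_expression(small_universe, truth, n_background_loci=50)
    return m, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
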