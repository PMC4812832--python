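import numpy as np
import pytest

from habitcoach.energy import FoodTable, MetTable
from habitcoach.synthetic_data import (
    ScenarioConfig,
    _random_profile,
    ground_truth_lifelog,
    simulate_user,
    user_rng,
)


@pytest.fixture(scope="session")
def met_table():
    return MetTable.default()


@pytest.fixture(scope="session")
def food_table():
    return FoodTable.default()


@pytest.fixture(scope="session")
def sim_user():
    """One 21-day simulated user (event-level, no sensor stream)."""
    profile = _random_profile("fix_user", user_rng(1, "fix_user/profile"))
    config = ScenarioConfig(days=21, seed=1)
    return simulate_user(profile, config, include_sensors=False)


@pytest.fixture(scope="session")
def sim_lifelog(sim_user):
    return ground_truth_lifelog(sim_user)


@pytest.fixture(scope="session")
def sim_clusters(sim_user, sim_lifelog, food_table):
    from habitcoach.behavior_clustering import cluster_lifelog

    return cluster_lifelog(sim_lifelog, food_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
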