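import numpy as np
import pytest

from thyraxis import (
    capacities_from_scaled,
    default_parameters,
)
from thyraxis.cohort_synth import CohortConfig, generate_cohort
from thyraxis.simulator import scenario_graves, scenario_hashimoto


@pytest.fixture(scope="session")
def default_params():
    return default_parameters()


@pytest.fixture(scope="session")
def hashimoto_params():
    _, k_p = capacities_from_scaled(0.0, 1.0)
    return default_parameters(k_t=0.0, k_p=k_p)


@pytest.fixture(scope="session")
def graves_params():
    k_t, _ = capacities_from_scaled(1.0, 0.0)
    return default_parameters(k_t=k_t, k_p=0.0)


@pytest.fixture(scope="session")
def hashimoto_loop(hashimoto_params):
    """Default Hashimoto disease + levothyroxine treatment trajectories."""
    return scenario_hashimoto(hashimoto_params)


@pytest.fixture(scope="session")
def graves_loop(graves_params):
    """Default Graves disease + antithyroid treatment trajectories."""
    return scenario_graves(graves_params)


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded synthetic Hashimoto cohort, shared across cohort tests."""
    return generate_cohort(CohortConfig(n_patients=50, seed=11))
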