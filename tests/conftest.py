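import warnings

import numpy as np
import pytest

from psychosense.design import DesignConfig
from psychosense.effects import fit_all_cells, threshold_differences
from psychosense.synth import SimCohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def design_config():
    return DesignConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """10 synthetic observers under the default study conditions."""
    cfg = SimCohortConfig(n_participants=10, seed=7)
    trials, truth = simulate_cohort(cfg)
    return trials, truth


@pytest.fixture(scope="session")
def small_fits(small_cohort, design_config):
    trials, _ = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_all_cells(trials, design_config)


@pytest.fixture(scope="session")
def small_effects(small_fits, design_config):
    return threshold_differences(small_fits, design_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
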