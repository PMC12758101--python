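import numpy as np
import pytest

from prtddm import (
    ActionDDMParams,
    CohortSpec,
    generate_schedule,
    simulate_cohort,
    simulate_subject,
)


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(seed=123)


@pytest.fixture(scope="session")
def base_params():
    return ActionDDMParams(alpha=0.15, B_v=0.4, B_z=0.8, v_intercept=1.5, a=1.0, t=0.3)


@pytest.fixture(scope="session")
def sim_subject(base_params, schedule):
    return simulate_subject(base_params, schedule, seed=7, subject_id="S1")


@pytest.fixture(scope="session")
def small_cohort():
    """Six simulated subjects with their ground-truth parameter table."""
    return simulate_cohort(CohortSpec(groups={"NC": 6}, seed=31))
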