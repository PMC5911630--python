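import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import survscreen as ss

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_cohort():
    """Small cohort with one strongly prognostic gene (PROG, HR = 2.2)."""
    cfg = ss.SimulationConfig(
        n_patients=400,
        n_genes=3,
        log_hr_by_gene={"PROG": np.log(2.2)},
        seed=11,
    )
    return ss.simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
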