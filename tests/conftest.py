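import numpy as np
import pandas as pd
import pytest

from seedscreen import ExpressionCohort
from seedscreen.synthetic import SurvivalSpec, SyntheticConfig, generate_cohorts


@pytest.fixture
def small_cohort() -> ExpressionCohort:
    """3 features x 6 samples with a planted linear relation to the seed."""
    seed = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    target = np.array([2.1, 3.9, 6.2, 7.8, 10.1, 11.9])
    rng = np.random.default_rng(0)
    null = rng.standard_normal(6)
    values = pd.DataFrame(
        [seed, target, null],
        index=["SEED", "T1", "N1"],
        columns=[f"s{i}" for i in range(6)],
    )
    return ExpressionCohort(cohort_id="toy", values=values)


@pytest.fixture(scope="session")
def eight_cohorts():
    """Eight study-sized cohorts, 20 planted (rho 0.5-0.7) + 79 null features."""
    cfg = SyntheticConfig(n_features=100, n_planted=20, rho_range=(0.5, 0.7), rng_seed=11)
    return generate_cohorts(cfg)


@pytest.fixture
def survival_spec() -> SurvivalSpec:
    return SurvivalSpec(baseline_hazard=1 / 500, hazard_ratio=2.0, censoring_rate=0.2)
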