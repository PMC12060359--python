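import numpy as np
import pytest

from epitwin.cohort import CohortDesign, TrueParams, generate_cohort


@pytest.fixture(scope="session")
def one_age_design():
    """Factory for a single-cohort design at a fixed age."""

    def make(n_mz, n_dz, mean_age=15.0, sd=0.0, gap=2.5):
        return CohortDesign(
            cohorts=(("solo", mean_age, sd, n_mz, n_dz),), occasion_gap=gap
        )

    return make


@pytest.fixture(scope="session")
def ace_table(one_age_design):
    """Mid-size ACE cohort (a2=.3, c2=.2, e2=.5 of unit variance), 1000+1000
    pairs at one age; reused across descriptive and model tests."""
    params = TrueParams(a0=np.sqrt(0.3), c0=np.sqrt(0.2), e0=np.sqrt(0.5))
    tab = generate_cohort(one_age_design(1000, 1000), params, seed=11)
    return tab.rename(columns={"value": "acceleration"})
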