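import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from frailvar import GGMParams, discretize_frailty, generate_poisson_cohort

# Human-range study parameters used throughout: Gompertz level anchored at
# calendar age 40, moderate senescence rate, small Makeham background,
# frailty variance 0.2.
STUDY = dict(a=0.02, b=0.1, c=0.005, gamma=0.2)


@pytest.fixture(scope="session")
def study_params():
    return GGMParams(start_age=40, **STUDY)


@pytest.fixture(scope="session")
def homogeneous_params():
    return GGMParams(a=0.02, b=0.1, c=0.005, gamma=0.0, start_age=40)


@pytest.fixture(scope="session")
def study_frailty():
    return discretize_frailty(STUDY["gamma"], g=200)


@pytest.fixture(scope="session")
def study_cohort(study_params):
    """One synthetic cohort at the study conditions (ages 40-109, n0=1e6)."""
    return generate_poisson_cohort(
        study_params, n0=1e6, n_ages=70, seed=20240, cohort_label="1850"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(99)
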