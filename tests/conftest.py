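import pytest

from scalesia_csm import CohortConfig, fit_survival_glmm
from scalesia_csm.synthetic_cohort import generate_cohort_frame


@pytest.fixture(scope="session")
def default_frame():
    """One study-scale cohort (426 plants, 10 sites) under default settings."""
    return generate_cohort_frame(CohortConfig(seed=20260926))


@pytest.fixture(scope="session")
def small_frame():
    """A small cohort that keeps GLMM fits fast."""
    return generate_cohort_frame(CohortConfig(n_plants=120, n_sites=4, seed=7))


@pytest.fixture(scope="session")
def small_fit(small_frame):
    return fit_survival_glmm(small_frame)
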