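import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from causalbag import synthetic_data as sd


@pytest.fixture(scope="session")
def study_scm():
    return sd.default_study_scm()


@pytest.fixture(scope="session")
def strong_scm():
    return sd.default_study_scm(strong=True)


@pytest.fixture(scope="session")
def study_cohort(study_scm):
    """Medium synthetic cohort from the realistic SCM."""
    return sd.generate_scm_cohort(study_scm, 5000, seed=42)


@pytest.fixture(scope="session")
def strong_cohort(strong_scm):
    """Cohort from the strong-coefficient SCM, n matching recovery tests."""
    return sd.generate_scm_cohort(strong_scm, 2000, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
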