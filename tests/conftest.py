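import numpy as np
import pytest

import gaitwear as gw


@pytest.fixture(scope="session")
def small_cohort():
    """Three short synthetic subjects; enough to exercise every stage."""
    return gw.default_cohort(3, seed=7, minutes=4.0)


@pytest.fixture(scope="session")
def small_session(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def cohort14():
    """Study-scale subject count with short sessions for model checks."""
    return gw.default_cohort(14, seed=gw.evaluation.DEFAULT_SEED, minutes=6.0)


@pytest.fixture(scope="session")
def dataset_a14(cohort14):
    return gw.build_dataset(cohort14, "A")


@pytest.fixture(scope="session")
def gait_report_a14(dataset_a14):
    """Nested LOSO, gait task, SVM, all sensors, reduced grid."""
    return gw.nested_loso(None, "gait", "A", "svm",
                          grid=gw.reduced_grid("svm"), dataset=dataset_a14)


@pytest.fixture(scope="session")
def default_cohort27():
    """The full default cohort: 14 subjects, ~27-minute sessions."""
    return gw.default_cohort(14, seed=gw.evaluation.DEFAULT_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
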