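import pytest

import rhinoflow as rf
from rhinoflow.geometry import SubjectState, default_template


@pytest.fixture(scope="session")
def ambient():
    return rf.AmbientConditions()


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def subject_pair():
    """A deviated preoperative airway and its fully corrected postoperative state."""
    pre = default_template("demo", SubjectState.PREOP, left_gap_factor=0.5,
                           right_gap_factor=1.1)
    post = default_template("demo", SubjectState.POSTOP, left_gap_factor=1.1,
                            right_gap_factor=1.1)
    return pre, post


@pytest.fixture(scope="session")
def protocol_result(subject_pair, ambient):
    pre, post = subject_pair
    return rf.run_subject_protocol(pre, post, ambient)


@pytest.fixture(scope="session")
def small_cohort():
    """Default eight-subject synthetic cohort with transport metrics."""
    return rf.generate_cohort(rf.CohortConfig(n_subjects=8, seed=1))


@pytest.fixture(scope="session")
def reference_cohort():
    return rf.load_reference_cohort()
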