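import numpy as np
import pytest

from aglnet.grammar import default_grammar
from aglnet.simulate import default_truth, make_schedule, simulate_group
from aglnet.usem import group_lagged_covariance


@pytest.fixture(scope="session")
def grammar():
    return default_grammar()


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def schedule():
    return make_schedule(8, 2.0)


@pytest.fixture(scope="session")
def planted_group(truth, schedule):
    """20 subjects x 176 scans from the 6-edge planted network."""
    return simulate_group(
        truth, schedule, n_subjects=20, between_subject_sd=0.02, seed=11
    )


@pytest.fixture(scope="session")
def planted_data(planted_group):
    return group_lagged_covariance(planted_group)
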