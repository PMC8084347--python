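import numpy as np
import pandas as pd
import pytest

from pdea.simulate import fixture_activity, make_fixture_cohort


@pytest.fixture(scope="session")
def cohort():
    return make_fixture_cohort(seed=1)


@pytest.fixture(scope="session")
def rpmi_activity(cohort):
    return fixture_activity(cohort, "RPMI")


@pytest.fixture(scope="session")
def dmem_activity(cohort):
    return fixture_activity(cohort, "DMEM")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def ranked_scores(rng):
    scores = pd.Series(rng.normal(0, 0.1, 200),
                       index=[f"G{i:03d}" for i in range(200)])
    return scores
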