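import numpy as np
import pandas as pd
import pytest

from circumplex_ssm import (
    DEFAULT_GEOMETRY,
    make_study_fixture,
    score_octants,
    score_scale,
    screen_protocols,
)


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def study_fixture():
    """The packaged 929-protocol synthetic study roster."""
    return make_study_fixture()


@pytest.fixture(scope="session")
def screened(study_fixture):
    """Screening result on the packaged fixture."""
    validity = score_scale(
        study_fixture.responses, study_fixture.keys["infrequency"], "infrequency"
    )
    return screen_protocols(study_fixture.responses, validity, study_fixture.rules)


@pytest.fixture(scope="session")
def retained_scores(study_fixture, screened):
    """Scale scores and problems-surface octant scores of retained rows."""
    retained = screened.retained
    octants = score_octants(retained, study_fixture.keys["problems"])
    scales = {
        name: score_scale(retained, study_fixture.keys["stpp"], name)
        for name in ("detachment", "social_anxiety", "psychoticism")
    }
    return scales, octants


def perfect_circumplex_matrix(k: int = 8, values=(0.6, 0.4, 0.2, 0.1)) -> np.ndarray:
    """Correlation matrix whose cells strictly decrease with distance class."""
    R = np.eye(k)
    for i in range(k):
        for j in range(k):
            if i != j:
                d = min(abs(i - j), k - abs(i - j))
                R[i, j] = values[d - 1]
    return R


@pytest.fixture(scope="session")
def perfect_matrix():
    return perfect_circumplex_matrix()
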