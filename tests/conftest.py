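import numpy as np
import pytest

from adherefit.sessions_io import DailySeries, PERIOD_DAYS
from adherefit.synthetic import CohortConfig, simulate_cohort


def make_series(user_id="u0", active_days=(), value=300.0, length=PERIOD_DAYS):
    """A daily series with ``value`` seconds on the given 1-based days."""
    values = np.zeros(length)
    for d in active_days:
        values[d - 1] = value
    return DailySeries(user_id=user_id, day_values=values)


@pytest.fixture
def small_cohort():
    """Deterministic 30-user synthetic cohort used by several suites."""
    return simulate_cohort(CohortConfig(n_users=30, seed=7))


SESSIONS_CSV = """\
user_id,start_time,duration_s,finished
u1,2021-01-01T08:00:00,100,true
u1,2021-01-01T18:30:00,50,YES
u1,2021-01-03T09:00:00,200,1
u2,2021-01-02T07:00:00,400,false
u2,2021-01-02T07:00:00,400,false
"""


@pytest.fixture
def sessions_csv():
    return SESSIONS_CSV
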