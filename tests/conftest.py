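import pandas as pd
import pytest

import screenuse as su


def make_events(rows):
    """Build an event frame from (participant_id, timestamp, state) tuples."""
    return pd.DataFrame(
        {
            "participant_id": [r[0] for r in rows],
            "timestamp": pd.to_datetime([r[1] for r in rows]),
            "state": [r[2] for r in rows],
        }
    )


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across the suite."""
    return su.simulate_cohort(su.SimConfig(seed=7))


@pytest.fixture(scope="session")
def pipeline_sessions(cohort):
    """The shared cohort's events run through the full sessionizer."""
    return su.sessionize(cohort.events)


@pytest.fixture(scope="session")
def dailies(pipeline_sessions):
    return su.daily_summaries(pipeline_sessions)
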