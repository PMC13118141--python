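from datetime import date

import pytest

from netrhythm import flow_io, synthetic


@pytest.fixture(scope="session")
def apps():
    return synthetic.default_apps()


@pytest.fixture(scope="session")
def routine_participant(apps):
    """One routine participant, 7 days, no dropout (frame, ground truth)."""
    return synthetic.simulate_participant(
        "P-routine", synthetic.ROUTINE, 7, apps, seed=11, start_day=date(2024, 3, 4)
    )


@pytest.fixture(scope="session")
def routine_series_10(routine_participant):
    frame, _ = routine_participant
    return flow_io.bin_traffic(frame, 10, -300)


@pytest.fixture(scope="session")
def small_cohort(apps):
    """Six participants (alternating phenotypes), 5 days, mild dropout."""
    config = synthetic.CohortConfig(n_participants=6, days=5, seed=7)
    return synthetic.simulate_cohort(config, apps=apps)
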