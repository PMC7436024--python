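import numpy as np
import pandas as pd
import pytest

import actiward as aw

SURGERY = pd.Timestamp("2019-03-04")


@pytest.fixture(scope="session")
def default_params():
    return aw.CohortParams(seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Analysis-ready 84-patient cohort frame with both outcomes."""
    return aw.simulate_outcomes(
        aw.CohortParams(n_control=61, n_intervention=23, seed=7)
    )


@pytest.fixture(scope="session")
def mixed_schedule():
    """A 90-minute ward episode with all four worn postures, second-aligned."""
    start = SURGERY + pd.Timedelta(days=1)
    return aw.hospital_day_schedule(
        start, active_min=30.0, wear_h=1.5, n_walk_bouts=3, seed=4
    )


@pytest.fixture(scope="session")
def noiseless_config():
    return aw.SensorConfig(noise_sd_g=0.0)


def schedule_window_oracle(schedule):
    """Map every covered whole second to the posture-implied label."""
    label_of = {
        "lying": "sedentary",
        "sitting": "sedentary",
        "standing": "standing",
        "walking": "dynamic",
    }
    oracle = {}
    for bout in schedule:
        if bout.posture == "nonwear":
            continue
        start = bout.start.ceil("s")
        n = int(np.floor((bout.end - start).total_seconds()))
        for k in range(n):
            sec = start + pd.Timedelta(seconds=k)
            if sec + pd.Timedelta(seconds=1) <= bout.end:
                oracle[sec] = label_of[bout.posture]
    return oracle
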