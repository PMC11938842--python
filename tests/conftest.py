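import numpy as np
import pandas as pd
import pytest

import chamberqc as cq


@pytest.fixture
def one_trial_3d():
    """Single 3-day trial, day 30 / night 24, day starts 06:00."""
    return cq.TrialConfig(
        trial_id="T1",
        day_setpoint=30.0,
        night_setpoint=24.0,
        day_hours=16.5,
        night_hours=7.5,
        window=("2021-03-01", "2021-03-04"),
    )


@pytest.fixture
def sim_3d(one_trial_3d):
    """Seeded 3-day single-sensor simulation with mild noise."""
    cfg = cq.SimConfig(
        trials=[one_trial_3d],
        sensors=[cq.SensorSpec("LC_Canopy_1", noise_sd=0.2)],
        seed=11,
    )
    return cq.simulate_chamber(cfg)


def series_from_values(values, start="2021-03-01", sensor="S", trial="T1"):
    values = np.asarray(values, dtype=float)
    grid = pd.date_range(start, periods=len(values), freq="min")
    return cq.SensorSeries.from_values(sensor, trial, grid, values)


@pytest.fixture
def make_series():
    return series_from_values
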