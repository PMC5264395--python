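"""Shared fixtures: small hand-built survey tables and simulated datasets."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from carnidens.survey import DeviceTable, bin_occasions, build_effort


@pytest.fixture
def mini_devices():
    """Four devices (2 cameras, 2 traps) over a 28-day window, always on."""
    xy = np.array([[0.0, 0.0], [500.0, 0.0], [250.0, 250.0], [750.0, 250.0]])
    return DeviceTable(
        ids=["cam0", "cam1", "trap0", "trap1"],
        xy=xy,
        device_class=np.array(["camera", "camera", "trap", "trap"]),
        survey_start=date(2013, 1, 15),
        operation=np.ones((4, 28), dtype=bool),
    )


@pytest.fixture
def mini_grid(mini_devices):
    return bin_occasions(28, 7, survey_start=mini_devices.survey_start)


@pytest.fixture
def mini_effort(mini_devices, mini_grid):
    return build_effort(mini_devices, mini_grid)


def make_events(rows):
    """Event DataFrame from (device_id, timestamp, species, ind, marked, c)."""
    df = pd.DataFrame(rows, columns=["device_id", "timestamp", "species",
                                     "individual_id", "marked", "n_animals"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


@pytest.fixture
def smr_sim():
    """Small-but-real SMR simulation reused across MCMC tests."""
    import carnidens as cd

    truth = cd.SimTruth(N=25, sigma=400.0, alpha0=np.log(0.05),
                        marked_fraction=0.3, n_collared=2, seed=42)
    return cd.simulate_survey(truth, n_cameras=25, n_traps=12, n_days=56)
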