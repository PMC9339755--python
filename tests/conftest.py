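"""Shared fixtures: small synthetic study setups generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from birdwind import attach_wind, decompose, make_network, make_wind_grid, simulate_profiles
from birdwind.synthetic_data import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A ten-night, three-radar study window in spring."""
    return SimulationConfig(
        n_radars=3,
        lat_range=(45.0, 50.0),
        lon_range=(2.0, 8.0),
        start_date="2018-04-01",
        end_date="2018-04-10",
        cadence="30min",
        n_altitude_bins=10,
    )


@pytest.fixture(scope="session")
def small_network(small_config):
    return make_network(small_config, seed=11)


@pytest.fixture(scope="session")
def small_grid(small_config):
    return make_wind_grid(small_config, seed=12)


@pytest.fixture(scope="session")
def small_sim(small_config, small_network, small_grid):
    """(records, truth) for the small spring window."""
    return simulate_profiles(small_network, small_grid, small_config, seed=13)


@pytest.fixture(scope="session")
def small_kinematics(small_sim, small_grid, small_network):
    """Wind-attached, decomposed records of the small window."""
    records, _ = small_sim
    attached = attach_wind(records, small_grid, small_network)
    assert attached.n_dropped == 0
    return decompose(attached.records)


@pytest.fixture()
def rng():
    return np.random.default_rng(20180715)


def make_profile_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a minimal VPTS-layout frame from row dicts (test helper)."""
    defaults = {"radar": "r0", "dens": 1.0, "sd_vvp": 2.0}
    out = []
    for row in rows:
        d = dict(defaults)
        d.update(row)
        out.append(d)
    df = pd.DataFrame(out)
    df["datetime"] = pd.to_datetime(df["datetime"])
    return df[["radar", "datetime", "height", "dens", "u", "v", "sd_vvp"]]
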