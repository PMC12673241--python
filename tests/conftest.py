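import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from thermoniche.synthetic import SyntheticWorldConfig, TemperatureCube, generate_world

logging.getLogger("thermoniche").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_config() -> SyntheticWorldConfig:
    """A compact world: 3 populations x 5 birds, 2-hourly fixes."""
    return SyntheticWorldConfig(
        n_populations=3,
        individuals_per_population=5,
        landscape_size_m=15_000.0,
        fix_interval_minutes=120.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)


def make_dense_cube(
    rng: np.random.Generator,
    n: int = 80,
    n_hours: int = 4,
    cell: float = 30.0,
    mean: float = 25.0,
    sd: float = 3.0,
) -> TemperatureCube:
    """A random dense (non-separable) raster cube for oracle tests."""
    hours = np.arange(
        np.datetime64("2021-06-01T00", "h"),
        np.datetime64("2021-06-01T00", "h") + np.timedelta64(n_hours, "h"),
    )
    data = rng.normal(mean, sd, size=(n_hours, n, n))
    return TemperatureCube(hours=hours, x0=cell / 2, y0=cell / 2, cell_size_m=cell, data=data)


def make_fixes(records) -> pd.DataFrame:
    """Build a fixes frame from (ind, pop, iso_ts, x, y, speed[, season]) tuples."""
    cols = ["individual_id", "population", "timestamp", "x", "y", "speed_ms"]
    if records and len(records[0]) == 7:
        cols.append("season")
    df = pd.DataFrame(records, columns=cols)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df.sort_values(["individual_id", "timestamp"]).reset_index(drop=True)
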