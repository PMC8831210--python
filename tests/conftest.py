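import numpy as np
import pandas as pd
import pytest

from phenotrap.series import TemperatureSeries


def hourly_series(
    temps, start="2000-01-01", site_id="s1", level="surface"
) -> TemperatureSeries:
    temps = np.asarray(temps, dtype=float)
    idx = pd.date_range(start, periods=len(temps), freq="h")
    return TemperatureSeries(site_id, level, pd.Series(temps, index=idx))


def constant_year(value, year=2000, site_id="s1", level="surface") -> TemperatureSeries:
    idx = pd.date_range(
        pd.Timestamp(year, 1, 1), pd.Timestamp(year, 12, 31, 23), freq="h"
    )
    return TemperatureSeries(site_id, level, pd.Series(float(value), index=idx))


def seeded_year(
    seed, year=2000, mean=6.0, amp=8.0, noise=2.0, site_id="s1", level="surface"
) -> TemperatureSeries:
    """Sinusoidal year plus white noise: generic test weather."""
    idx = pd.date_range(
        pd.Timestamp(year, 1, 1), pd.Timestamp(year, 12, 31, 23), freq="h"
    )
    rng = np.random.default_rng(seed)
    t = np.arange(len(idx))
    temps = (
        mean
        - amp * np.cos(2 * np.pi * t / len(idx))
        + rng.normal(0, noise, len(idx))
    )
    return TemperatureSeries(site_id, level, pd.Series(temps, index=idx))


@pytest.fixture
def make_hourly():
    return hourly_series


@pytest.fixture
def make_constant_year():
    return constant_year


@pytest.fixture
def make_seeded_year():
    return seeded_year
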