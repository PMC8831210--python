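"""Hourly temperature containers shared across the pipeline.

All timestamps are timezone-naive and interpreted as UTC.  Each hourly
timestamp labels the *start* of its hour, so the value at ``2000-01-01 13:00``
is the temperature of the hour 13:00-14:00.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

#: Canonical vertical levels the simulator produces.
SURFACE = "surface"
SOIL_10 = "soil_010"
SOIL_50 = "soil_050"
AIR = "air"
#: Derived level: element-wise mean of the 10 cm and 50 cm soil traces,
#: standing in for the upper region of an overwintering refuge.
HIBERNACULUM = "hibernaculum"

LEVELS = (SURFACE, SOIL_10, SOIL_50, AIR)

#: Depth below ground (m) each canonical level represents; air is modelled
#: at z = 0 with an offset.
LEVEL_DEPTH_M = {SURFACE: 0.0, SOIL_10: 0.10, SOIL_50: 0.50, AIR: 0.0}

ONE_HOUR_NS = 3_600_000_000_000


def validate_hourly_index(index: pd.DatetimeIndex, *, context: str = "") -> None:
    """Raise ``ValueError`` unless ``index`` is strictly hourly with no gaps
    inside any calendar year (whole missing years are tolerated, matching
    occurrence datasets with gap years)."""
    if len(index) == 0:
        raise ValueError(f"empty timestamp index {context}")
    if not index.is_monotonic_increasing:
        raise ValueError(f"timestamps not increasing {context}")
    deltas = np.diff(index.asi8)
    bad = np.flatnonzero(deltas != ONE_HOUR_NS)
    for i in bad:
        a, b = index[i], index[i + 1]
        if deltas[i] <= 0:
            raise ValueError(f"duplicate or reversed timestamp at {b} {context}")
        # a gap is allowed only if it spans complete calendar years
        if not (
            a == pd.Timestamp(a.year, 12, 31, 23)
            and b == pd.Timestamp(b.year, 1, 1, 0)
        ):
            raise ValueError(
                f"gap in hourly series between {a} and {b} {context}"
            )


@dataclass
class TemperatureSeries:
    """One site's hourly temperature trace (degC) at a single vertical level."""

    site_id: str
    level: str
    data: pd.Series  # float degC, hourly DatetimeIndex

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise TypeError("TemperatureSeries requires a DatetimeIndex")
        validate_hourly_index(
            self.data.index, context=f"(site={self.site_id}, level={self.level})"
        )
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError(
                f"non-finite temperatures (site={self.site_id}, level={self.level})"
            )

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def temps(self) -> np.ndarray:
        return self.data.to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def slice(self, start: pd.Timestamp, end: pd.Timestamp) -> "TemperatureSeries":
        """Inclusive slice; raises if the window is not fully covered."""
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        idx = self.data.index
        if start < idx[0] or end > idx[-1]:
            raise ValueError(
                f"window [{start}, {end}] outside series span "
                f"[{idx[0]}, {idx[-1]}] (site={self.site_id}, level={self.level})"
            )
        return TemperatureSeries(self.site_id, self.level, self.data.loc[start:end])

    def year_slice(self, year: int) -> "TemperatureSeries":
        sub = self.data.loc[str(year)]
        if len(sub) == 0:
            raise KeyError(f"no data for year {year} (site={self.site_id})")
        return TemperatureSeries(self.site_id, self.level, sub)

    def years(self) -> list[int]:
        return sorted(set(self.data.index.year))


@dataclass
class DegreeHourSeries:
    """Cumulative degree-hours above ``base_temp`` (degC h).

    ``data[t]`` is the heat accumulated over all complete hours *before*
    instant ``t`` (and at or after ``accumulation_start``), so the value at
    midnight of a date is the accumulation through the end of the previous
    day.  Non-decreasing by construction; zero at and before the start.
    """

    site_id: str
    data: pd.Series
    base_temp: float
    accumulation_start: pd.Timestamp

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    def value_at(self, when: pd.Timestamp) -> float:
        return float(self.data.loc[pd.Timestamp(when)])

    @property
    def year(self) -> int:
        return int(self.accumulation_start.year)


class SeriesStore:
    """In-memory keyed collection of :class:`TemperatureSeries`.

    Keyed by ``(site_id, level)``; each entry may span multiple years.
    """

    def __init__(self) -> None:
        self._series: dict[tuple[str, str], TemperatureSeries] = {}

    def add(self, series: TemperatureSeries) -> None:
        self._series[(series.site_id, series.level)] = series

    def get(self, site_id: str, level: str) -> TemperatureSeries:
        try:
            return self._series[(site_id, level)]
        except KeyError:
            raise KeyError(f"no series for site={site_id!r} level={level!r}") from None

    def has(self, site_id: str, level: str) -> bool:
        return (site_id, level) in self._series

    def sites(self) -> list[str]:
        return sorted({s for s, _ in self._series})

    def levels(self, site_id: str) -> list[str]:
        return sorted({lv for s, lv in self._series if s == site_id})

    def items(self) -> Iterator[tuple[tuple[str, str], TemperatureSeries]]:
        return iter(sorted(self._series.items()))

    def years(self, site_id: str, level: str) -> list[int]:
        return self.get(site_id, level).years()

    def __len__(self) -> int:
        return len(self._series)


# ---------------------------------------------------------------------------
# Study windows

def spring_window(year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Sighting/search window: Jan 1 00:00 to May 31 23:00 inclusive."""
    return pd.Timestamp(year, 1, 1), pd.Timestamp(year, 5, 31, 23)


def frost_window(year: int, end_month: int = 6) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Spring frost-accounting window.

    Ends Jun 30 23:00 by default; ``end_month=5`` gives the stricter
    May 31 23:00 variant.
    """
    if end_month == 6:
        return pd.Timestamp(year, 1, 1), pd.Timestamp(year, 6, 30, 23)
    if end_month == 5:
        return pd.Timestamp(year, 1, 1), pd.Timestamp(year, 5, 31, 23)
    raise ValueError("frost window must end in May or June")


def day_of_year(when: pd.Timestamp) -> float:
    """Fractional days since Jan 1 00:00 of the focal year (Jan 1 00:00 = 0.0)."""
    when = pd.Timestamp(when)
    return float((when - pd.Timestamp(when.year, 1, 1)) / pd.Timedelta(days=1))
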