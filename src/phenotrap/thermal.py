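"""Core temperature arithmetic: degree-hours, depth means, rolling means,
frost-hour counts.

Degree-hours are the linear accumulated-temperature currency used throughout:
each hour contributes ``max(T - base, 0) * 1 h`` (degC h).  No nonlinear
(sine-method) degree-day formulation is provided; development is assumed
linear in temperature above the base.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .series import HIBERNACULUM, DegreeHourSeries, TemperatureSeries

__all__ = [
    "accumulate_degree_hours",
    "annual_degree_hours",
    "depth_mean_series",
    "rolling_mean",
    "frost_hours",
]


def accumulate_degree_hours(
    series: TemperatureSeries,
    base_temp: float = 7.0,
    start: pd.Timestamp | None = None,
) -> DegreeHourSeries:
    """Cumulative degree-hours above ``base_temp`` from ``start``.

    The returned series shares the input's hourly index.  The value at
    instant ``t`` sums the positive excesses of all hours completed strictly
    before ``t`` (zero at and before ``start``); with a constant 8 degC trace
    and base 7, the value at hour 21 is exactly 21 degC h.

    Parameters
    ----------
    series
        Hourly temperature trace.
    base_temp
        Development base (degC); 7 degC is the package default, the
        approximate critical minimum for locomotion in temperate vipers.
    start
        Accumulation start instant; defaults to the first timestamp.
    """
    idx = series.timestamps
    if start is None:
        start = idx[0]
    start = pd.Timestamp(start)
    if start < idx[0] or start > idx[-1]:
        raise ValueError(f"accumulation start {start} outside series span")
    excess = np.clip(series.temps - float(base_temp), 0.0, None)
    excess[idx < start] = 0.0
    cum = np.cumsum(excess)
    dh = np.empty_like(cum)
    dh[0] = 0.0
    dh[1:] = cum[:-1]
    return DegreeHourSeries(
        site_id=series.site_id,
        data=pd.Series(dh, index=idx),
        base_temp=float(base_temp),
        accumulation_start=start,
    )


def annual_degree_hours(
    series: TemperatureSeries, base_temp: float = 7.0
) -> dict[int, DegreeHourSeries]:
    """Per-year degree-hour accumulations, each restarting Jan 1 00:00.

    Spring accumulation is computed per calendar year; the year boundary is
    Jan 1 00:00 and each year's accumulator starts from zero.
    """
    out: dict[int, DegreeHourSeries] = {}
    for year in series.years():
        sub = series.year_slice(year)
        out[year] = accumulate_degree_hours(sub, base_temp, start=sub.timestamps[0])
    return out


def depth_mean_series(
    t10: TemperatureSeries, t50: TemperatureSeries
) -> TemperatureSeries:
    """Element-wise mean of the 10 cm and 50 cm traces.

    The result is tagged with the derived ``hibernaculum`` level: it stands
    for the average temperature of the upper refuge region to which a
    hibernating animal is assumed to equilibrate.
    """
    if t10.site_id != t50.site_id:
        raise ValueError(
            f"depth mean across different sites: {t10.site_id!r} vs {t50.site_id!r}"
        )
    if not t10.timestamps.equals(t50.timestamps):
        raise ValueError(f"misaligned timestamps for site {t10.site_id!r}")
    mean = (t10.data.to_numpy() + t50.data.to_numpy()) / 2.0
    return TemperatureSeries(
        t10.site_id, HIBERNACULUM, pd.Series(mean, index=t10.timestamps)
    )


def rolling_mean(series: TemperatureSeries, window: int) -> pd.Series:
    """Trailing mean over the last ``window`` hours (window includes the
    current hour).  Undefined positions (the first ``window - 1`` hours)
    are NaN.
    """
    window = int(window)
    if window < 1:
        raise ValueError("window must be >= 1 hour")
    if window > len(series):
        raise ValueError(
            f"window {window} h exceeds series length {len(series)} h"
        )
    return series.data.rolling(window, min_periods=window).mean()


def frost_hours(
    series: TemperatureSeries,
    start: pd.Timestamp,
    end: pd.Timestamp,
    threshold: float = 0.0,
) -> int:
    """Number of hours in ``[start, end]`` (inclusive) at or below
    ``threshold`` degC.  The comparison is inclusive: an hour at exactly
    0.0 degC counts as a ground-frost hour.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start > end:
        raise ValueError("frost window start after end")
    sub = series.slice(start, end)
    return int(np.count_nonzero(sub.temps <= float(threshold)))
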