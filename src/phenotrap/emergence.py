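"""Emergence-cue calibration and per-site-year emergence prediction.

Four cue models are supported:

* ``accumulated_threshold`` -- emergence at the first hour the cumulative
  degree-hour total (base 7 degC, hibernaculum depth-mean trace) reaches a
  threshold calibrated as a low percentile of the totals observed at
  sighting dates.  Sightings happen at an unknown delay after true
  emergence, so a low percentile (default 5th) of the sighting values is
  taken as the trigger.
* ``sharp_rise`` -- emergence at the end of the window over which
  accumulated degree-hours increased fastest.
* ``gradient_collapse`` -- emergence when the winter temperature-depth
  profile reverses (10 cm daily mean exceeds 50 cm daily mean).
* ``air_rolling_mean`` -- emergence when a trailing rolling mean of
  near-surface air temperature first reaches a critical value (10 degC).

An auxiliary ``absolute_temperature`` trigger (percentile of the maximum
hibernaculum temperature reached before each sighting) is exposed behind
the same calibration interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import DegreeHourSeries, TemperatureSeries, spring_window
from .thermal import rolling_mean

logger = logging.getLogger(__name__)

__all__ = [
    "CueConfig",
    "EmergenceThreshold",
    "EmergencePrediction",
    "sighting_degree_hours",
    "sighting_peak_temperature",
    "calibrate_threshold",
    "predict_emergence",
    "predict_emergence_gradient_collapse",
    "predict_emergence_air",
    "predict_emergence_sharp_rise",
    "run_emergence_stage",
]

CUES = (
    "accumulated_threshold",
    "sharp_rise",
    "gradient_collapse",
    "air_rolling_mean",
)


@dataclass(frozen=True)
class CueConfig:
    """Cue model and its tunable parameters.

    ``percentile`` is a fraction (0.05 = 5th percentile); the 2.5th and
    10th are the standard sensitivity alternatives.  ``air_window`` and
    ``rise_window`` are documented free parameters (hours).
    """

    cue: str = "accumulated_threshold"
    base_temp: float = 7.0
    percentile: float = 0.05
    air_threshold: float = 10.0
    air_window: int = 240
    rise_window: int = 240

    def __post_init__(self) -> None:
        if self.cue not in CUES:
            raise ValueError(f"unknown cue {self.cue!r}")
        if not (0.0 < self.percentile < 1.0):
            raise ValueError("percentile must lie in (0, 1)")
        if not np.isfinite(self.base_temp):
            raise ValueError("base_temp must be finite")


@dataclass(frozen=True)
class EmergenceThreshold:
    value: float  # degC h (or degC for the absolute-temperature trigger)
    cue: str
    percentile: float
    n_sightings: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("threshold must be >= 0")
        if self.n_sightings < 1:
            raise ValueError("threshold requires at least one sighting")


@dataclass(frozen=True)
class EmergencePrediction:
    site_id: str
    year: int
    emergence_time: pd.Timestamp  # NaT when the cue never fires
    dh_at_emergence: float  # NaN when absent or cue has no degree-hour value

    @property
    def emerged(self) -> bool:
        return not pd.isna(self.emergence_time)


def _absent(site_id: str, year: int) -> EmergencePrediction:
    return EmergencePrediction(site_id, int(year), pd.NaT, float("nan"))


# ---------------------------------------------------------------------------
# Calibration

def sighting_degree_hours(
    sightings: pd.DataFrame,
    dh_store: dict[tuple[str, int], DegreeHourSeries],
) -> pd.DataFrame:
    """Cumulative degree-hours accumulated before each sighting.

    The value is the degree-hour total at 00:00 of the sighting date, i.e.
    the accumulation over all complete hours before that date.  Input order
    is preserved; sightings whose site-year has no degree-hour series are
    skipped with a logged warning.
    """
    rows = []
    n_missing = 0
    for i, rec in sightings.iterrows():
        date = pd.Timestamp(rec["date"]).normalize()
        key = (rec["site_id"], int(date.year))
        dh = dh_store.get(key)
        if dh is None:
            n_missing += 1
            continue
        rows.append(
            {
                "site_id": rec["site_id"],
                "date": date,
                "value": dh.value_at(date),
            }
        )
    if n_missing:
        logger.warning(
            "sighting_degree_hours: skipped %d sightings with no matching series",
            n_missing,
        )
    return pd.DataFrame(rows, columns=["site_id", "date", "value"])


def sighting_peak_temperature(
    sightings: pd.DataFrame,
    temp_store: dict[tuple[str, int], TemperatureSeries],
) -> pd.DataFrame:
    """Maximum hibernaculum temperature reached before each sighting date
    (the absolute-temperature analogue of :func:`sighting_degree_hours`)."""
    rows = []
    n_missing = 0
    for _, rec in sightings.iterrows():
        date = pd.Timestamp(rec["date"]).normalize()
        key = (rec["site_id"], int(date.year))
        ts = temp_store.get(key)
        if ts is None:
            n_missing += 1
            continue
        before = ts.data.loc[: date - pd.Timedelta(hours=1)]
        if len(before) == 0:
            continue
        rows.append(
            {"site_id": rec["site_id"], "date": date, "value": float(before.max())}
        )
    if n_missing:
        logger.warning(
            "sighting_peak_temperature: skipped %d sightings with no series",
            n_missing,
        )
    return pd.DataFrame(rows, columns=["site_id", "date", "value"])


def calibrate_threshold(
    values: np.ndarray | pd.Series | list[float],
    percentile: float = 0.05,
    cue: str = "accumulated_threshold",
) -> EmergenceThreshold:
    """Empirical quantile of the sighting values at ``percentile``.

    Uses linear interpolation between order statistics (the "type 7"
    convention, numpy's default), fixed here so results are reproducible.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("cannot calibrate a threshold from zero sightings")
    if not (0.0 < percentile < 1.0):
        raise ValueError("percentile must lie in (0, 1)")
    value = float(np.quantile(arr, percentile, method="linear"))
    return EmergenceThreshold(
        value=value, cue=cue, percentile=float(percentile), n_sightings=int(arr.size)
    )


# ---------------------------------------------------------------------------
# Prediction under each cue

def _threshold_value(threshold: EmergenceThreshold | float) -> float:
    if isinstance(threshold, EmergenceThreshold):
        return float(threshold.value)
    return float(threshold)


def predict_emergence(
    dh: DegreeHourSeries, threshold: EmergenceThreshold | float
) -> EmergencePrediction:
    """First hour in the spring search window at which the cumulative
    degree-hour total reaches the threshold; absent if never reached by
    May 31 23:00."""
    thr = _threshold_value(threshold)
    year = dh.year
    w0, w1 = spring_window(year)
    idx = dh.timestamps
    if idx[0] > w0 or idx[-1] < w1:
        raise ValueError(
            f"degree-hour series does not cover the spring window of {year}"
        )
    window = dh.data.loc[w0:w1]
    values = window.to_numpy()
    hit = np.flatnonzero(values >= thr)
    if hit.size == 0:
        return _absent(dh.site_id, year)
    t = window.index[hit[0]]
    return EmergencePrediction(dh.site_id, year, t, float(values[hit[0]]))


def predict_emergence_gradient_collapse(
    t10: TemperatureSeries,
    t50: TemperatureSeries,
    daily: bool = True,
) -> EmergencePrediction:
    """Emergence when the shallow trace first exceeds the deep one.

    By default the comparison is on daily means: brief daytime reversals
    of the near-surface profile occur even in mid-winter, so raw-hour
    comparison (``daily=False``) fires unrealistically early and is exposed
    only as an option.
    """
    if t10.site_id != t50.site_id or not t10.timestamps.equals(t50.timestamps):
        raise ValueError("gradient collapse requires aligned same-site series")
    year = int(t10.timestamps[0].year)
    w0, w1 = spring_window(year)
    a = t10.data.loc[w0:w1]
    b = t50.data.loc[w0:w1]
    if daily:
        a = a.resample("D").mean()
        b = b.resample("D").mean()
    diff = a.to_numpy() - b.to_numpy()
    hit = np.flatnonzero(diff > 0.0)
    if hit.size == 0:
        return _absent(t10.site_id, year)
    return EmergencePrediction(
        t10.site_id, year, pd.Timestamp(a.index[hit[0]]), float("nan")
    )


def predict_emergence_air(
    air: TemperatureSeries, config: CueConfig | None = None
) -> EmergencePrediction:
    """Emergence at the first hour the trailing ``air_window``-hour mean of
    air temperature reaches ``air_threshold``."""
    cfg = config or CueConfig(cue="air_rolling_mean")
    year = int(air.timestamps[0].year)
    w0, w1 = spring_window(year)
    if len(air) < cfg.air_window:
        raise ValueError("air series shorter than the rolling window")
    rm = rolling_mean(air, cfg.air_window)
    window = rm.loc[w0:w1]
    values = window.to_numpy()
    hit = np.flatnonzero(values >= cfg.air_threshold)
    if hit.size == 0:
        return _absent(air.site_id, year)
    return EmergencePrediction(
        air.site_id, year, pd.Timestamp(window.index[hit[0]]), float("nan")
    )


def predict_emergence_sharp_rise(
    dh: DegreeHourSeries, rise_window: int = 240
) -> EmergencePrediction:
    """Emergence at the end of the ``rise_window``-hour interval (within the
    spring window) over which accumulated degree-hours increased the most;
    ties break to the earliest interval.  Absent when nothing accumulates.
    """
    rise_window = int(rise_window)
    year = dh.year
    w0, w1 = spring_window(year)
    window = dh.data.loc[w0:w1]
    if rise_window >= len(window):
        raise ValueError("rise window longer than the spring series")
    v = window.to_numpy()
    gains = v[rise_window:] - v[:-rise_window]
    best = int(np.argmax(gains))  # argmax takes the earliest maximum
    if gains[best] <= 0.0:
        return _absent(dh.site_id, year)
    t = window.index[best + rise_window]
    return EmergencePrediction(dh.site_id, year, pd.Timestamp(t), float(v[best + rise_window]))


# ---------------------------------------------------------------------------
# Full stage

def run_emergence_stage(
    sightings: pd.DataFrame,
    dh_store: dict[tuple[str, int], DegreeHourSeries],
    config: CueConfig | None = None,
) -> tuple[EmergenceThreshold, list[EmergencePrediction]]:
    """Calibrate the accumulated-threshold cue on all sightings pooled
    across sites and years, then predict emergence for every site-year in
    the store (not only sighting years)."""
    cfg = config or CueConfig()
    if len(sightings) == 0:
        raise ValueError("emergence stage requires at least one sighting")
    values = sighting_degree_hours(sightings, dh_store)
    threshold = calibrate_threshold(values["value"], cfg.percentile, cue=cfg.cue)
    predictions = [
        predict_emergence(dh_store[key], threshold) for key in sorted(dh_store)
    ]
    n_absent = sum(not p.emerged for p in predictions)
    if n_absent:
        logger.info(
            "run_emergence_stage: cue never fired in %d of %d site-years",
            n_absent,
            len(predictions),
        )
    return threshold, predictions
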