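"""Synthetic site microclimate and occurrence-record generator.

The hourly temperature model is the analytic solution of heat conduction in
a homogeneous half-space forced by annual and diurnal surface harmonics:

    T(z, t) = mean + w * (year - year0)
              + A_ann * exp(-z/d_ann) * sin(w_ann * t + phi - z/d_ann)
              + A_diu * exp(-z/d_diu) * sin(w_diu * t - z/d_diu)
              + noise

so depth attenuates amplitude by ``exp(-z/d)`` and delays phase by ``z/d``
radians, exactly as in real soil profiles.  Weather noise is an AR(1)
process generated once at the surface per site and attenuated with depth by
``exp(-z/noise_depth_scale)``; all levels of a site share the same
innovation stream and are therefore vertically correlated.  The air level
is the surface solution plus a mean offset, carrying the full noise.

Sighting records emulate opportunistic occurrence data: each record is a
true emergence date (under a known cue and threshold) plus a non-negative
reporting lag, truncated to the spring recording window.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .series import (
    AIR,
    LEVEL_DEPTH_M,
    LEVELS,
    SOIL_10,
    SOIL_50,
    SURFACE,
    SeriesStore,
    TemperatureSeries,
    spring_window,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClimateParams",
    "SiteConfig",
    "SightingGenParams",
    "COASTAL_PRESET",
    "INLAND_PRESET",
    "simulate_temperature_series",
    "simulate_site",
    "make_sites",
    "make_trap_scenario",
    "generate_sightings",
    "true_emergence_schedule",
]

#: Angular frequency of the annual cycle (rad per hour, 365.25-day year).
OMEGA_ANNUAL = 2.0 * np.pi / (365.25 * 24.0)
#: Angular frequency of the diurnal cycle (rad per hour).
OMEGA_DIURNAL = 2.0 * np.pi / 24.0

#: Annual phase placing the surface minimum around Jan 20 (nothern
#: mid-winter) when t is counted from Jan 1 00:00 of the first year.
DEFAULT_ANNUAL_PHASE = float(-np.pi / 2.0 - OMEGA_ANNUAL * 468.0)


@dataclass(frozen=True)
class ClimateParams:
    """Parameters of one site's harmonic climate.

    Units: temperatures degC, depths m, rates degC/year, phase radians.
    """

    mean_temp: float = 9.0
    annual_amplitude: float = 6.0
    diurnal_amplitude: float = 3.0
    diurnal_amplitude_seasonal: float = 0.0
    annual_phase: float = DEFAULT_ANNUAL_PHASE
    damping_depth_annual: float = 2.0
    damping_depth_diurnal: float = 0.12
    warming_rate: float = 0.04
    noise_sd: float = 1.5
    noise_ar1: float = 0.85
    noise_depth_scale: float = 0.15
    air_offset: float = -0.5

    def __post_init__(self) -> None:
        if self.annual_amplitude < 0 or self.diurnal_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if abs(self.diurnal_amplitude_seasonal) > self.diurnal_amplitude:
            raise ValueError(
                "seasonal diurnal modulation cannot exceed the mean diurnal "
                "amplitude (instantaneous amplitude would go negative)"
            )
        if self.damping_depth_annual <= 0 or self.damping_depth_diurnal <= 0:
            raise ValueError("damping depths must be > 0")
        if not (0.0 <= self.noise_ar1 < 1.0):
            raise ValueError("noise_ar1 must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_depth_scale <= 0:
            raise ValueError("noise_depth_scale must be > 0")


@dataclass(frozen=True)
class SiteConfig:
    site_id: str
    latitude: float
    longitude: float
    coastal: bool  # distance to coastline <= 3 km
    climate: ClimateParams = field(default_factory=ClimateParams)

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude} out of range")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude {self.longitude} out of range")


@dataclass(frozen=True)
class SightingGenParams:
    """Controls the opportunistic-record generator.

    ``true_cue``/``true_threshold`` define the ground-truth emergence
    trigger; ``lag_distribution`` is the reporting delay between true
    emergence and the recorded sighting date.
    """

    true_cue: str = "accumulated_threshold"
    true_threshold: float = 21.0  # degC h
    base_temp: float = 7.0
    lag_distribution: str = "uniform"  # zero | uniform | exponential
    lag_days: float = 10.0
    sightings_per_year: int | dict[int, int] = 10
    years: tuple[int, int] = (1983, 2017)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_threshold <= 0:
            raise ValueError("true_threshold must be > 0")
        if self.lag_days < 0:
            raise ValueError("lag parameter must be >= 0")
        if self.lag_distribution not in ("zero", "uniform", "exponential"):
            raise ValueError(f"unknown lag distribution {self.lag_distribution!r}")
        y0, y1 = self.years
        if y1 < y0:
            raise ValueError("empty year range")


# ---------------------------------------------------------------------------
# Scenario presets.
#
# Documented constants, not fitted values and not claims about any real
# region.  The coastal preset has low seasonality (maritime climate): frost
# is marginal and spread thinly across the spring, the degree-hour ramp is
# shallow, so a fixed warming shift advances emergence by many days while
# frost depletes slowly -- the configuration in which phenological
# advancement overcompensates frost depletion.  The inland preset has high
# seasonality: frost is concentrated in deep winter and depletes quickly,
# while emergence shifts little.

COASTAL_PRESET = ClimateParams(
    mean_temp=8.2,
    annual_amplitude=4.5,
    diurnal_amplitude=3.0,
    diurnal_amplitude_seasonal=0.0,
    damping_depth_annual=2.0,
    warming_rate=0.04,
    noise_sd=1.5,
    noise_ar1=0.85,
    noise_depth_scale=0.15,
)

INLAND_PRESET = ClimateParams(
    mean_temp=7.2,
    annual_amplitude=7.0,
    diurnal_amplitude=5.0,
    diurnal_amplitude_seasonal=4.5,
    damping_depth_annual=2.0,
    warming_rate=0.04,
    noise_sd=1.5,
    noise_ar1=0.85,
    noise_depth_scale=0.15,
)


def _years_tuple(years: tuple[int, int]) -> tuple[int, int]:
    y0, y1 = int(years[0]), int(years[1])
    if y1 < y0:
        raise ValueError(f"empty year range {years}")
    return y0, y1


def hourly_index(years: tuple[int, int]) -> pd.DatetimeIndex:
    y0, y1 = _years_tuple(years)
    return pd.date_range(
        pd.Timestamp(y0, 1, 1), pd.Timestamp(y1, 12, 31, 23), freq="h"
    )


def _site_rng(seed: int, site_id: str) -> np.random.Generator:
    # site identity enters through a stable CRC so different sites draw
    # independent streams while every level of one site shares a stream
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(site_id.encode("utf8"))])
    )


def simulate_temperature_series(
    site: SiteConfig,
    level: str,
    years: tuple[int, int],
    seed: int = 0,
) -> TemperatureSeries:
    """Simulate one site/level hourly trace for the inclusive year range.

    Deterministic given ``(site, level, years, seed)``.  The warming trend
    is applied as ``warming_rate * (calendar year - first year)``, so the
    noise-free annual mean steps up by exactly the warming rate each year.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    y0, y1 = _years_tuple(years)
    idx = hourly_index((y0, y1))
    p = site.climate
    z = LEVEL_DEPTH_M[level]
    t = np.arange(len(idx), dtype=np.float64)

    temps = np.full(len(idx), p.mean_temp, dtype=np.float64)
    temps += p.warming_rate * (idx.year.to_numpy() - y0)
    temps += (
        p.annual_amplitude
        * np.exp(-z / p.damping_depth_annual)
        * np.sin(OMEGA_ANNUAL * t + p.annual_phase - z / p.damping_depth_annual)
    )
    # diurnal range may itself vary seasonally (continental sites see a much
    # larger diurnal cycle in summer than in winter); the modulation tracks
    # the annual phase so the range peaks with the seasonal maximum
    diurnal_amp = p.diurnal_amplitude + p.diurnal_amplitude_seasonal * np.sin(
        OMEGA_ANNUAL * t + p.annual_phase
    )
    temps += (
        diurnal_amp
        * np.exp(-z / p.damping_depth_diurnal)
        * np.sin(OMEGA_DIURNAL * t - z / p.damping_depth_diurnal)
    )
    if level == AIR:
        temps += p.air_offset

    if p.noise_sd > 0:
        rng = _site_rng(seed, site.site_id)
        innovations = rng.normal(0.0, p.noise_sd, len(idx))
        surface_noise = lfilter([1.0], [1.0, -p.noise_ar1], innovations)
        atten = 1.0 if level == AIR else np.exp(-z / p.noise_depth_scale)
        temps += atten * surface_noise

    return TemperatureSeries(site.site_id, level, pd.Series(temps, index=idx))


def simulate_site(
    site: SiteConfig,
    years: tuple[int, int],
    seed: int = 0,
    levels: tuple[str, ...] = LEVELS,
) -> SeriesStore:
    """Simulate a store holding the requested levels for one site."""
    store = SeriesStore()
    for level in levels:
        store.add(simulate_temperature_series(site, level, years, seed))
    return store


def make_sites(
    n: int,
    scenario: str = "mixed",
    seed: int = 0,
    warming_rate: float | None = None,
) -> list[SiteConfig]:
    """Build ``n`` site configurations for a study scenario.

    ``scenario`` is ``coastal``, ``inland`` or ``mixed`` (alternating).
    Site-to-site heterogeneity is a small seeded jitter on the preset mean
    temperature and annual amplitude, standing in for mesoclimatic variation
    between locations.
    """
    if scenario not in ("coastal", "inland", "mixed"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51735]))
    sites: list[SiteConfig] = []
    for i in range(int(n)):
        coastal = scenario == "coastal" or (scenario == "mixed" and i % 2 == 0)
        preset = COASTAL_PRESET if coastal else INLAND_PRESET
        params = replace(
            preset,
            mean_temp=preset.mean_temp + rng.normal(0.0, 0.3),
            annual_amplitude=max(
                0.5, preset.annual_amplitude + rng.normal(0.0, 0.3)
            ),
        )
        if warming_rate is not None:
            params = replace(params, warming_rate=float(warming_rate))
        # generic south-west peninsular coordinates with jitter
        lat = 50.2 + rng.normal(0.0, 0.15)
        lon = -5.0 + rng.normal(0.0, 0.35)
        sites.append(
            SiteConfig(
                site_id=f"site_{i:03d}",
                latitude=float(lat),
                longitude=float(lon),
                coastal=coastal,
                climate=params,
            )
        )
    return sites


def make_trap_scenario(
    kind: str, years: tuple[int, int] = (1983, 2017), seed: int = 0
) -> tuple[SiteConfig, SeriesStore]:
    """Single-site preset scenario for mechanism studies.

    ``coastal`` is parameterized so that, under the default pipeline, the
    site-level trend in post-emergence frost hours is positive (warming
    advances emergence faster than frost depletes); ``inland`` yields a
    negative trend.  The presets are frozen module constants.
    """
    if kind == "coastal":
        site = SiteConfig("coastal_trap", 49.97, -5.20, True, COASTAL_PRESET)
    elif kind == "inland":
        site = SiteConfig("inland_ref", 50.55, -4.60, False, INLAND_PRESET)
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")
    return site, simulate_site(site, years, seed)


# ---------------------------------------------------------------------------
# Sightings

def true_emergence_schedule(
    site: SiteConfig,
    store: SeriesStore,
    params: SightingGenParams,
) -> dict[int, pd.Timestamp | None]:
    """Ground-truth emergence date (a midnight) per year under the
    generating cue.

    Records carry dates, not hours, so the generator defines emergence at
    day resolution: the animal counts as emerged from the first day whose
    00:00 already satisfies the cue condition (the hourly cue-firing
    instant rounded up to the next midnight).  ``None`` marks a year in
    which the cue never fires by May 31.
    """
    from . import emergence  # deferred: emergence depends on thermal only
    from .thermal import annual_degree_hours, depth_mean_series

    y0, y1 = params.years
    out: dict[int, pd.Timestamp | None] = {}
    cue = params.true_cue
    if cue in ("accumulated_threshold", "sharp_rise"):
        hib = depth_mean_series(
            store.get(site.site_id, SOIL_10), store.get(site.site_id, SOIL_50)
        )
        dh_by_year = annual_degree_hours(hib, params.base_temp)
    for year in range(y0, y1 + 1):
        if cue == "accumulated_threshold":
            pred = emergence.predict_emergence(dh_by_year[year], params.true_threshold)
        elif cue == "sharp_rise":
            pred = emergence.predict_emergence_sharp_rise(dh_by_year[year])
        elif cue == "gradient_collapse":
            pred = emergence.predict_emergence_gradient_collapse(
                store.get(site.site_id, SOIL_10).year_slice(year),
                store.get(site.site_id, SOIL_50).year_slice(year),
            )
        elif cue == "air_rolling_mean":
            pred = emergence.predict_emergence_air(
                store.get(site.site_id, AIR).year_slice(year)
            )
        else:
            raise ValueError(f"unknown true cue {cue!r}")
        out[year] = pred.emergence_time.ceil("D") if pred.emerged else None
    return out


def _draw_lags_days(
    rng: np.random.Generator, params: SightingGenParams, n: int
) -> np.ndarray:
    if params.lag_distribution == "zero" or params.lag_days == 0:
        return np.zeros(n)
    if params.lag_distribution == "uniform":
        return rng.uniform(0.0, params.lag_days, n)
    return rng.exponential(params.lag_days, n)


def generate_sightings(
    sites: list[SiteConfig],
    params: SightingGenParams,
    store: SeriesStore,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw opportunistic sighting records with known ground truth.

    Returns ``(sightings, truth)``:

    * ``sightings`` -- columns ``site_id, latitude, longitude, date``; one
      row per record, date = true emergence date + reporting lag, clamped
      to the Jan 1 - May 31 recording window.
    * ``truth`` -- columns ``site_id, year, true_emergence``; the exact
      emergence instants (NaT where the cue never fired), for test use.

    Site-years where the cue never fires emit no sightings (counted in the
    log).  Reproducible under ``params.seed``.
    """
    y0, y1 = params.years
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 0x5167]))

    schedules = {
        s.site_id: true_emergence_schedule(s, store, params) for s in sites
    }
    truth_rows = [
        {
            "site_id": sid,
            "year": year,
            "true_emergence": ts if ts is not None else pd.NaT,
        }
        for sid, sched in schedules.items()
        for year, ts in sched.items()
    ]

    rows = []
    n_silent = 0
    for year in range(y0, y1 + 1):
        if isinstance(params.sightings_per_year, dict):
            n_year = int(params.sightings_per_year.get(year, 0))
        else:
            n_year = int(params.sightings_per_year)
        if n_year == 0:
            continue
        picks = rng.integers(0, len(sites), n_year)
        lags = _draw_lags_days(rng, params, n_year)
        for k, lag in zip(picks, lags):
            site = sites[int(k)]
            true_ts = schedules[site.site_id][year]
            if true_ts is None:
                n_silent += 1
                continue
            date = (true_ts + pd.Timedelta(days=float(lag))).normalize()
            _, w1 = spring_window(year)
            last_date = w1.normalize()
            if date > last_date:
                date = last_date
            rows.append(
                {
                    "site_id": site.site_id,
                    "latitude": site.latitude,
                    "longitude": site.longitude,
                    "date": date,
                }
            )
    if n_silent:
        logger.info("generate_sightings: %d draws fell in cue-silent site-years", n_silent)
    sightings = pd.DataFrame(
        rows, columns=["site_id", "latitude", "longitude", "date"]
    )
    truth = pd.DataFrame(truth_rows, columns=["site_id", "year", "true_emergence"])
    return sightings, truth
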