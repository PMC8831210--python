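"""CSV readers and writers for every pipeline artifact.

Formats (all plain CSV, timestamps ISO-8601, implicitly UTC):

* temperature store -- long format: ``site_id, level, timestamp, temp_c``
* sites            -- ``site_id, latitude, longitude, coastal`` plus the
  climate parameters when written by the simulator
* sightings        -- ``site_id, latitude, longitude, date``
* stage outputs    -- predictions, exposures, trends, traps
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .microclimate import ClimateParams, SiteConfig
from .series import SeriesStore, TemperatureSeries, spring_window, validate_hourly_index

logger = logging.getLogger(__name__)

__all__ = [
    "read_sightings",
    "write_sightings",
    "read_temperature_store",
    "write_temperature_store",
    "read_sites",
    "write_sites",
]

SIGHTING_COLUMNS = ("site_id", "date")
STORE_COLUMNS = ("site_id", "level", "timestamp", "temp_c")


def read_sightings(path: str | Path) -> pd.DataFrame:
    """Parse a sightings CSV.

    Unparseable dates are reported with their row numbers; records outside
    the Jan 1 - May 31 spring window are dropped with a logged count (the
    upstream screening rule that removes summer records), and exact
    ``site_id + date`` duplicates are removed.
    """
    df = pd.read_csv(path, dtype={"site_id": str})
    missing = [c for c in SIGHTING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sightings file {path} missing columns: {missing}")
    parsed = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(parsed.isna().to_numpy() & df["date"].notna().to_numpy())
    if bad.size:
        rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(
            f"sightings file {path}: unparseable dates at rows {rows}"
        )
    df = df.assign(date=parsed.dt.normalize()).dropna(subset=["date"])

    in_window = pd.Series(False, index=df.index)
    for year, group in df.groupby(df["date"].dt.year):
        w0, w1 = spring_window(int(year))
        in_window.loc[group.index] = group["date"].between(w0, w1.normalize())
    n_out = int((~in_window).sum())
    if n_out:
        logger.info("read_sightings: dropped %d records outside Jan 1 - May 31", n_out)
    df = df.loc[in_window]

    before = len(df)
    df = df.drop_duplicates(subset=["site_id", "date"]).reset_index(drop=True)
    n_dup = before - len(df)
    if n_dup:
        logger.info("read_sightings: dropped %d duplicate records", n_dup)
    if len(df) == 0:
        logger.warning("read_sightings: %s yielded no usable records", path)
    return df


def write_sightings(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_temperature_store(store: SeriesStore, path: str | Path) -> None:
    frames = []
    for (site_id, level), series in store.items():
        frames.append(
            pd.DataFrame(
                {
                    "site_id": site_id,
                    "level": level,
                    "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                    "temp_c": series.temps,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_temperature_store(path: str | Path) -> SeriesStore:
    """Load a long-format temperature CSV into an indexed store.

    Rows may arrive in any order; hourly continuity within each calendar
    year is validated per site/level and a gap or duplicate timestamp is a
    hard error naming the first offending instant.
    """
    df = pd.read_csv(
        path, dtype={"site_id": str, "level": str}, float_precision="round_trip"
    )
    missing = [c for c in STORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"temperature store {path} missing columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    store = SeriesStore()
    for (site_id, level), group in df.groupby(["site_id", "level"]):
        group = group.sort_values("timestamp")
        idx = pd.DatetimeIndex(group["timestamp"])
        if idx.has_duplicates:
            first = idx[idx.duplicated()][0]
            raise ValueError(
                f"duplicate timestamp {first} (site={site_id}, level={level})"
            )
        validate_hourly_index(idx, context=f"(site={site_id}, level={level})")
        store.add(
            TemperatureSeries(
                site_id, level, pd.Series(group["temp_c"].to_numpy(), index=idx)
            )
        )
    return store


_CLIMATE_FIELDS = [f.name for f in dataclasses.fields(ClimateParams)]


def write_sites(sites: list[SiteConfig], path: str | Path) -> None:
    rows = []
    for s in sites:
        row = {
            "site_id": s.site_id,
            "latitude": s.latitude,
            "longitude": s.longitude,
            "coastal": s.coastal,
        }
        row.update({k: getattr(s.climate, k) for k in _CLIMATE_FIELDS})
        rows.append(row)
    # %.17g guarantees float round-trip to the bit
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_sites(path: str | Path, coastal_km: float = 3.0) -> list[SiteConfig]:
    """Read a sites CSV.

    The ``coastal`` flag may be given directly or derived from a
    ``distance_to_coast_km`` column using the ``coastal_km`` rule (default
    3 km).  Climate-parameter columns, when present, populate each site's
    :class:`ClimateParams`.
    """
    df = pd.read_csv(path, dtype={"site_id": str}, float_precision="round_trip")
    for col in ("site_id", "latitude", "longitude"):
        if col not in df.columns:
            raise ValueError(f"sites file {path} missing column {col!r}")
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"].iloc[0]
        raise ValueError(f"duplicate site_id {dup!r} in {path}")
    sites = []
    for _, row in df.iterrows():
        if "coastal" in df.columns:
            coastal = bool(row["coastal"])
        elif "distance_to_coast_km" in df.columns:
            coastal = float(row["distance_to_coast_km"]) <= coastal_km
        else:
            raise ValueError(
                f"sites file {path} needs a coastal or distance_to_coast_km column"
            )
        climate_kwargs = {
            k: float(row[k]) for k in _CLIMATE_FIELDS if k in df.columns
        }
        sites.append(
            SiteConfig(
                site_id=str(row["site_id"]),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                coastal=coastal,
                climate=ClimateParams(**climate_kwargs),
            )
        )
    return sites
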