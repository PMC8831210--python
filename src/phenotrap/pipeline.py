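"""End-to-end driver: simulate/ingest -> calibrate -> predict -> expose ->
trends -> traps, with per-stage CSV outputs and a reproducibility manifest.

Deterministic given the config (all randomness flows from ``config.seed``);
rerunning the same config writes byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import StudyConfig
from .emergence import (
    CueConfig,
    EmergencePrediction,
    EmergenceThreshold,
    predict_emergence_air,
    predict_emergence_gradient_collapse,
    predict_emergence_sharp_rise,
    run_emergence_stage,
)
from .exposure import FrostExposure, post_emergence_frost
from .io import (
    read_sightings,
    read_sites,
    read_temperature_store,
    write_sightings,
    write_sites,
    write_temperature_store,
)
from .microclimate import (
    AIR,
    SOIL_10,
    SOIL_50,
    SURFACE,
    SightingGenParams,
    SiteConfig,
    generate_sightings,
    make_sites,
    simulate_temperature_series,
)
from .series import DegreeHourSeries, SeriesStore, day_of_year
from .thermal import annual_degree_hours, depth_mean_series
from .trends import (
    TrendResult,
    classify_traps,
    coastal_contrast,
    emergence_frost_correlation,
    pooled_trend,
    site_trend,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "build_degree_hour_store"]


@dataclass
class PipelineResult:
    config: StudyConfig
    sites: list[SiteConfig]
    sightings: pd.DataFrame
    threshold: EmergenceThreshold | None
    predictions: pd.DataFrame
    exposures: pd.DataFrame
    pooled_trends: dict[str, TrendResult]
    site_trends: pd.DataFrame
    correlation: tuple[float, float, int]
    traps: pd.DataFrame
    contrast: object
    summary: dict


def build_degree_hour_store(
    store: SeriesStore, base_temp: float = 7.0
) -> dict[tuple[str, int], DegreeHourSeries]:
    """Per site-year degree-hour accumulations on the hibernaculum
    (10/50 cm depth-mean) trace, restarting each Jan 1."""
    out: dict[tuple[str, int], DegreeHourSeries] = {}
    for site_id in store.sites():
        hib = depth_mean_series(
            store.get(site_id, SOIL_10), store.get(site_id, SOIL_50)
        )
        for year, dh in annual_degree_hours(hib, base_temp).items():
            out[(site_id, year)] = dh
    return out


def _levels_needed(cue: str) -> tuple[str, ...]:
    levels = [SURFACE, SOIL_10, SOIL_50]
    if cue == "air_rolling_mean":
        levels.append(AIR)
    return tuple(levels)


def _predict_all(
    store: SeriesStore,
    dh_store: dict[tuple[str, int], DegreeHourSeries],
    sightings: pd.DataFrame,
    cfg: CueConfig,
) -> tuple[EmergenceThreshold | None, list[EmergencePrediction]]:
    if cfg.cue == "accumulated_threshold":
        return run_emergence_stage(sightings, dh_store, cfg)
    predictions = []
    for site_id, year in sorted(dh_store):
        if cfg.cue == "sharp_rise":
            pred = predict_emergence_sharp_rise(
                dh_store[(site_id, year)], cfg.rise_window
            )
        elif cfg.cue == "gradient_collapse":
            pred = predict_emergence_gradient_collapse(
                store.get(site_id, SOIL_10).year_slice(year),
                store.get(site_id, SOIL_50).year_slice(year),
            )
        else:  # air_rolling_mean
            pred = predict_emergence_air(
                store.get(site_id, AIR).year_slice(year), cfg
            )
        predictions.append(pred)
    return None, predictions


def run_pipeline(config: StudyConfig) -> PipelineResult:
    """Execute the full inference chain and write all stage outputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.cue_config()

    # -- stage: inputs ------------------------------------------------------
    if config.scenario == "files":
        if not (config.sightings_path and config.sites_path and config.store_path):
            raise ValueError("scenario 'files' requires sightings, sites and store paths")
        sites = read_sites(config.sites_path, config.coastal_km)
        store = read_temperature_store(config.store_path)
        sightings = read_sightings(config.sightings_path)
    else:
        sites = make_sites(config.n_sites, config.scenario, config.seed)
        store = SeriesStore()
        for site in sites:
            for level in _levels_needed(cfg.cue):
                store.add(
                    simulate_temperature_series(site, level, config.years, config.seed)
                )
        gen = SightingGenParams(
            true_cue=config.true_cue,
            true_threshold=config.true_threshold,
            base_temp=config.base_temp,
            lag_distribution=config.lag_distribution,
            lag_days=config.lag_days,
            sightings_per_year=config.sightings_per_year,
            years=config.years,
            seed=config.seed,
        )
        sightings, _truth = generate_sightings(sites, gen, store)
    logger.info("inputs: %d sites, %d sightings", len(sites), len(sightings))
    coastal_by_site = {s.site_id: s.coastal for s in sites}
    site_by_id = {s.site_id: s for s in sites}

    # -- stage: calibrate + predict -----------------------------------------
    dh_store = build_degree_hour_store(store, config.base_temp)
    threshold, predictions = _predict_all(store, dh_store, sightings, cfg)
    pred_rows = []
    for p in predictions:
        pred_rows.append(
            {
                "site_id": p.site_id,
                "year": p.year,
                "emergence_timestamp": p.emergence_time,
                "emergence_doy": day_of_year(p.emergence_time) if p.emerged else np.nan,
                "dh_at_emergence": p.dh_at_emergence,
                "cue": cfg.cue,
                "percentile": cfg.percentile,
            }
        )
    predictions_df = pd.DataFrame(pred_rows)
    logger.info(
        "emergence: threshold=%s, %d/%d site-years emerged",
        f"{threshold.value:.2f}" if threshold else "n/a",
        int(predictions_df["emergence_timestamp"].notna().sum()),
        len(predictions_df),
    )

    # -- stage: exposure -----------------------------------------------------
    exp_rows = []
    for p in predictions:
        surface = store.get(p.site_id, SURFACE).year_slice(p.year)
        e: FrostExposure = post_emergence_frost(
            surface, p, config.frost_threshold, config.frost_end_month
        )
        exp_rows.append(
            {
                "site_id": e.site_id,
                "year": e.year,
                "total_spring_frost_h": e.total_spring_frost_h,
                "post_emergence_frost_h": e.post_emergence_frost_h,
                "emergence_timestamp": e.emergence_time,
                "coastal": coastal_by_site.get(e.site_id, False),
            }
        )
    exposures_df = pd.DataFrame(exp_rows)

    # -- stage: trends -------------------------------------------------------
    panel = exposures_df.merge(
        predictions_df[["site_id", "year", "emergence_doy"]], on=["site_id", "year"]
    )
    pooled = {
        "spring_frost": pooled_trend(
            panel.rename(columns={"total_spring_frost_h": "v"}), "v", config.trend_method
        ),
        "emergence_doy": pooled_trend(panel, "emergence_doy", config.trend_method),
        "post_emergence_frost": pooled_trend(
            panel.rename(columns={"post_emergence_frost_h": "v"}), "v", config.trend_method
        ),
    }
    pooled = {
        k: TrendResult(t.scope, k, t.slope, t.slope_se, t.statistic, t.p_value, t.n, t.method)
        for k, t in pooled.items()
    }

    em_trends: dict[str, TrendResult] = {}
    fr_trends: dict[str, TrendResult] = {}
    site_rows = []
    for site_id, g in panel.groupby("site_id"):
        em = site_trend(g["year"], g["emergence_doy"], "emergence_doy", site_id)
        fr = site_trend(
            g["year"], g["post_emergence_frost_h"], "post_emergence_frost", site_id
        )
        if em is not None:
            em_trends[site_id] = em
        if fr is not None:
            fr_trends[site_id] = fr
        for t in (em, fr):
            if t is not None:
                site_rows.append(
                    {
                        "scope": "site",
                        "site_id": site_id,
                        "response": t.response,
                        "slope": t.slope,
                        "se": t.slope_se,
                        "stat": t.statistic,
                        "p": t.p_value,
                        "n": t.n,
                        "method": t.method,
                    }
                )
    site_trends_df = pd.DataFrame(site_rows)

    correlation = emergence_frost_correlation(
        panel["emergence_doy"], panel["post_emergence_frost_h"]
    )
    traps = classify_traps(
        em_trends, fr_trends, coastal_by_site, config.emergence_alpha, config.frost_rule
    )
    traps_df = pd.DataFrame(
        [
            {
                "site_id": t.site_id,
                "coastal": t.coastal,
                "emergence_trend": t.emergence_trend,
                "frost_trend": t.frost_trend,
                "trap_flag": t.trap_flag,
            }
            for t in traps
        ]
    )
    try:
        contrast = coastal_contrast(exposures_df, config.contrast_method)
    except ValueError:
        contrast = None  # single-group study
    n_traps = int(traps_df["trap_flag"].sum()) if len(traps_df) else 0

    summary = {
        "n_sites": len(sites),
        "n_sightings": int(len(sightings)),
        "threshold_dh": threshold.value if threshold else None,
        "emergence_trend_days_per_year": pooled["emergence_doy"].slope,
        "spring_frost_trend_h_per_year": pooled["spring_frost"].slope,
        "post_emergence_frost_trend_h_per_year": pooled["post_emergence_frost"].slope,
        "emergence_frost_r": correlation[0],
        "n_trap_sites": n_traps,
        "coastal_contrast_h": contrast.estimate if contrast else None,
    }
    logger.info("summary: %s", summary)

    # -- stage: outputs ------------------------------------------------------
    write_sites(sites, out_dir / "sites.csv")
    write_sightings(sightings, out_dir / "sightings.csv")
    if config.write_store:
        write_temperature_store(store, out_dir / "temperature_store.csv")
    _write_timestamped(predictions_df, out_dir / "predictions.csv")
    _write_timestamped(exposures_df, out_dir / "exposures.csv")

    pooled_rows = [
        {
            "scope": "pooled",
            "site_id": "",
            "response": t.response,
            "slope": t.slope,
            "se": t.slope_se,
            "stat": t.statistic,
            "p": t.p_value,
            "n": t.n,
            "method": t.method,
        }
        for t in pooled.values()
    ]
    trends_df = pd.concat(
        [pd.DataFrame(pooled_rows), site_trends_df], ignore_index=True
    )
    trends_df.to_csv(out_dir / "trends.csv", index=False)
    traps_df.to_csv(out_dir / "traps.csv", index=False)
    pd.DataFrame(
        [
            {
                "site_id": t.site_id,
                "longitude": site_by_id[t.site_id].longitude,
                "latitude": site_by_id[t.site_id].latitude,
                "frost_trend": t.frost_trend,
            }
            for t in traps
            if t.site_id in site_by_id
        ]
    ).to_csv(out_dir / "site_map.csv", index=False)

    manifest = {
        "package": "phenotrap",
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "row_counts": {
            "sites": len(sites),
            "sightings": int(len(sightings)),
            "predictions": int(len(predictions_df)),
            "exposures": int(len(exposures_df)),
            "trends": int(len(trends_df)),
            "traps": int(len(traps_df)),
        },
        "summary": summary,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")

    return PipelineResult(
        config=config,
        sites=sites,
        sightings=sightings,
        threshold=threshold,
        predictions=predictions_df,
        exposures=exposures_df,
        pooled_trends=pooled,
        site_trends=site_trends_df,
        correlation=correlation,
        traps=traps_df,
        contrast=contrast,
        summary=summary,
    )


def _write_timestamped(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
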