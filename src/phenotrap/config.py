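"""Study configuration: every window, threshold and seed in one place.

Defaults are the study's printed values: 7 degC degree-hour base, 5th
percentile calibration, 0 degC frost threshold, 3 km coastal rule, Jan 1 -
May 31 sighting/search window and a frost window running through June.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .emergence import CueConfig


@dataclass
class StudyConfig:
    # data sources: synthetic scenario by default, CSV paths otherwise
    scenario: str = "mixed"  # coastal | inland | mixed | files
    n_sites: int = 20
    years: tuple[int, int] = (1983, 2017)
    seed: int = 0
    sightings_path: str | None = None
    sites_path: str | None = None
    store_path: str | None = None

    # sighting generator (study conditions)
    sightings_per_year: int = 10
    lag_distribution: str = "uniform"
    lag_days: float = 10.0
    true_cue: str = "accumulated_threshold"
    true_threshold: float = 21.0

    # cue / calibration
    cue: str = "accumulated_threshold"
    base_temp: float = 7.0
    percentile: float = 0.05
    air_threshold: float = 10.0
    air_window: int = 240
    rise_window: int = 240

    # exposure
    frost_threshold: float = 0.0
    frost_end_month: int = 6  # June inclusive; 5 for the May 31 variant

    # trends / traps
    trend_method: str = "auto"
    emergence_alpha: float = 0.05
    frost_rule: str = "sign"
    contrast_method: str = "mean"
    coastal_km: float = 3.0

    # output
    out_dir: str = "phenotrap_out"
    write_store: bool = False

    def cue_config(self) -> CueConfig:
        return CueConfig(
            cue=self.cue,
            base_temp=self.base_temp,
            percentile=self.percentile,
            air_threshold=self.air_threshold,
            air_window=self.air_window,
            rise_window=self.rise_window,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "years" in d:
            d = dict(d)
            d["years"] = tuple(d["years"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
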