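"""Spring ground-frost exposure, overall and after predicted emergence.

A ground-frost hour is an hour with surface temperature <= 0 degC.  Total
spring frost counts over Jan 1 - Jun 30; post-emergence frost counts from
the predicted emergence hour (inclusive) to the same window end.  Exposure
is the endpoint -- no freeze-tolerance or mortality model sits behind it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .series import TemperatureSeries, frost_window
from .thermal import frost_hours
from .emergence import EmergencePrediction

__all__ = ["FrostExposure", "spring_frost_total", "post_emergence_frost"]


@dataclass(frozen=True)
class FrostExposure:
    """Per site-year frost accounting (hours at or below the threshold)."""

    site_id: str
    year: int
    total_spring_frost_h: int
    post_emergence_frost_h: float  # NaN when emergence is absent
    emergence_time: pd.Timestamp  # NaT when absent

    @property
    def emerged(self) -> bool:
        return not pd.isna(self.emergence_time)


def spring_frost_total(
    surface: TemperatureSeries,
    year: int,
    threshold: float = 0.0,
    end_month: int = 6,
) -> int:
    """Ground-frost hours over the whole spring window of ``year``."""
    w0, w1 = frost_window(year, end_month)
    return frost_hours(surface, w0, w1, threshold)


def post_emergence_frost(
    surface: TemperatureSeries,
    prediction: EmergencePrediction,
    threshold: float = 0.0,
    end_month: int = 6,
) -> FrostExposure:
    """Frost hours between predicted emergence (inclusive) and the window
    end.  An absent emergence yields an absent (NaN) exposure; such
    site-years are excluded from downstream trend fits.
    """
    year = prediction.year
    w0, w1 = frost_window(year, end_month)
    total = frost_hours(surface, w0, w1, threshold)
    if not prediction.emerged:
        return FrostExposure(prediction.site_id, year, total, float("nan"), pd.NaT)
    t_em = pd.Timestamp(prediction.emergence_time)
    if t_em < w0 or t_em > w1:
        raise ValueError(
            f"emergence {t_em} outside the frost window [{w0}, {w1}]"
        )
    post = frost_hours(surface, t_em, w1, threshold)
    return FrostExposure(
        prediction.site_id, year, total, float(post), t_em
    )
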