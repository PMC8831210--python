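"""Temporal trend estimation, the emergence-frost correlation, and
climate-trap classification.

Pooled trends come from a linear mixed model with year as a fixed effect
and a random intercept per site; site-specific trends are ordinary least
squares against year.  A "climate trap" site is one whose emergence timing
trend is significantly negative (earlier emergence) while its
post-emergence frost exposure trend is positive -- phenological advancement
outpacing within-season frost depletion.  No multiple-testing correction is
applied across sites; flag counts are reported at the nominal level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TrendResult",
    "TrapAssessment",
    "ContrastResult",
    "pooled_trend",
    "site_trend",
    "emergence_frost_correlation",
    "classify_traps",
    "coastal_contrast",
]


@dataclass(frozen=True)
class TrendResult:
    scope: str  # pooled | site
    response: str
    slope: float  # response units per year
    slope_se: float
    statistic: float
    p_value: float
    n: int
    method: str = "ols"

    def __post_init__(self) -> None:
        if self.slope_se < 0:
            raise ValueError("slope SE must be >= 0")
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value out of [0, 1]")


@dataclass(frozen=True)
class TrapAssessment:
    site_id: str
    coastal: bool
    emergence_trend: float  # days/year
    frost_trend: float  # hours/year
    trap_flag: bool


@dataclass(frozen=True)
class ContrastResult:
    estimate: float  # inland minus coastal
    se: float
    statistic: float
    p_value: float
    n_inland: int
    n_coastal: int
    method: str


def _clean_panel(panel: pd.DataFrame, response: str) -> pd.DataFrame:
    df = panel[["site_id", "year", response]].dropna()
    df = df.rename(columns={response: "value"})
    df["year"] = df["year"].astype(float)
    return df


def _within_site_trend(df: pd.DataFrame, response: str) -> TrendResult:
    """Within-site centered regression: demean response and year inside each
    site, regress through the origin.  For balanced panels this equals the
    random-intercept slope; residual df charges one parameter per site."""
    g = df.groupby("site_id")
    x = (df["year"] - g["year"].transform("mean")).to_numpy()
    y = (df["value"] - g["value"].transform("mean")).to_numpy()
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("degenerate panel: no within-site year variation")
    slope = float(np.dot(x, y) / sxx)
    resid = y - slope * x
    dof = len(df) - df["site_id"].nunique() - 1
    rss = float(np.dot(resid, resid))
    if dof <= 0 or rss <= 0.0:
        se, tstat, p = 0.0, float("inf") if slope != 0 else 0.0, 0.0 if slope != 0 else 1.0
    else:
        se = float(np.sqrt(rss / dof / sxx))
        tstat = slope / se
        p = float(2.0 * stats.t.sf(abs(tstat), dof))
    return TrendResult("pooled", response, slope, se, float(tstat), p, len(df), "within")


def pooled_trend(
    panel: pd.DataFrame, response: str, method: str = "auto"
) -> TrendResult:
    """Year slope across all sites with site-level intercepts.

    ``panel`` needs columns ``site_id``, ``year`` and ``response``.
    ``method``:

    * ``"mixed"``  -- REML linear mixed model (random intercept per site),
      Wald z test on the year slope;
    * ``"within"`` -- within-site centered OLS (exact for balanced panels);
    * ``"auto"``   -- mixed, falling back to within when the variance-
      components fit fails or degenerates (e.g. zero residual variance).
    """
    df = _clean_panel(panel, response)
    if df["year"].nunique() < 2:
        raise ValueError("pooled trend requires at least two distinct years")
    if method not in ("auto", "mixed", "within"):
        raise ValueError(f"unknown trend method {method!r}")
    if method in ("auto", "mixed"):
        try:
            import statsmodels.api as sm

            yc = df["year"] - df["year"].mean()
            exog = np.column_stack([np.ones(len(df)), yc.to_numpy()])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.MixedLM(
                    df["value"].to_numpy(), exog, groups=df["site_id"].to_numpy()
                ).fit(reml=True)
            slope = float(fit.params[1])
            se = float(fit.bse[1])
            if np.isfinite(slope) and np.isfinite(se) and se > 0:
                z = slope / se
                p = float(2.0 * stats.norm.sf(abs(z)))
                return TrendResult(
                    "pooled", response, slope, se, float(z), p, len(df), "mixed"
                )
            if method == "mixed":
                raise RuntimeError("mixed fit degenerated (non-finite or zero SE)")
        except Exception:
            if method == "mixed":
                raise
            logger.info(
                "pooled_trend(%s): mixed fit failed, using within-site centering",
                response,
            )
    return _within_site_trend(df, response)


def site_trend(
    years: np.ndarray | pd.Series,
    values: np.ndarray | pd.Series,
    response: str = "",
    site_id: str = "",
) -> TrendResult | None:
    """OLS slope of one site's annual values against year.

    Returns ``None`` (with a log entry) when fewer than three years carry
    data, matching the minimum for a meaningful slope.
    """
    x = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3 or np.unique(x).size < 3:
        logger.info("site_trend(%s, %s): <3 years with data, skipped", site_id, response)
        return None
    res = stats.linregress(x, y)
    slope, se = float(res.slope), float(res.stderr)
    if se == 0.0 or not np.isfinite(se):
        # exact line or constant series: p degenerates
        tstat = float("inf") if slope != 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
        se = 0.0
    else:
        tstat = slope / se
        p = float(res.pvalue)
    return TrendResult("site", response, slope, se, tstat, p, int(x.size), "ols")


def emergence_frost_correlation(
    emergence_doy: np.ndarray | pd.Series,
    post_frost_h: np.ndarray | pd.Series,
) -> tuple[float, float, int]:
    """Pearson product-moment correlation between emergence day-of-year and
    post-emergence frost hours, pooled over site-years.

    Returns ``(r, two-sided p, n)``.  A negative r is the trap-consistent
    sign: earlier emergence, more subsequent frost.
    """
    x = np.asarray(emergence_doy, dtype=float)
    y = np.asarray(post_frost_h, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("correlation requires at least three pairs")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def classify_traps(
    emergence_trends: dict[str, TrendResult],
    frost_trends: dict[str, TrendResult],
    coastal: dict[str, bool],
    emergence_alpha: float = 0.05,
    frost_rule: str = "sign",
) -> list[TrapAssessment]:
    """Flag sites whose emergence advanced while post-emergence frost rose.

    A site is flagged when its emergence slope is negative and significant
    at ``emergence_alpha`` and its frost slope is positive; ``frost_rule``
    chooses between sign-only (default) and ``"significant"`` (p below the
    same alpha) on the frost trend.  Sites missing either trend are skipped.
    """
    if frost_rule not in ("sign", "significant"):
        raise ValueError(f"unknown frost rule {frost_rule!r}")
    out: list[TrapAssessment] = []
    for site_id in sorted(set(emergence_trends) & set(frost_trends)):
        em = emergence_trends[site_id]
        fr = frost_trends[site_id]
        if em is None or fr is None:
            continue
        advancing = em.slope < 0 and (
            emergence_alpha is None or em.p_value < emergence_alpha
        )
        frost_up = fr.slope > 0
        if frost_rule == "significant":
            frost_up = frost_up and fr.p_value < emergence_alpha
        out.append(
            TrapAssessment(
                site_id=site_id,
                coastal=bool(coastal.get(site_id, False)),
                emergence_trend=em.slope,
                frost_trend=fr.slope,
                trap_flag=bool(advancing and frost_up),
            )
        )
    return out


def coastal_contrast(
    exposures: pd.DataFrame, method: str = "mean"
) -> ContrastResult:
    """Inland-minus-coastal contrast in post-emergence frost exposure.

    ``exposures`` needs columns ``post_emergence_frost_h`` and ``coastal``
    (boolean).  ``method="mean"`` (default) regresses the frost-hour count
    on an inland indicator, giving the difference in expected hours with
    its SE; ``method="logistic"`` regresses a binarized any-frost outcome,
    giving a log-odds contrast.
    """
    import statsmodels.api as sm

    df = exposures.dropna(subset=["post_emergence_frost_h"])
    inland = (~df["coastal"].astype(bool)).to_numpy(dtype=float)
    y = df["post_emergence_frost_h"].to_numpy(dtype=float)
    n_inland = int(inland.sum())
    n_coastal = int(len(df) - n_inland)
    if n_inland == 0 or n_coastal == 0:
        raise ValueError("coastal contrast requires both groups non-empty")
    exog = np.column_stack([np.ones(len(df)), inland])
    if method == "mean":
        fit = sm.OLS(y, exog).fit()
    elif method == "logistic":
        fit = sm.Logit((y > 0).astype(float), exog).fit(disp=0)
    else:
        raise ValueError(f"unknown contrast method {method!r}")
    est, se = float(fit.params[1]), float(fit.bse[1])
    stat = est / se if se > 0 else (0.0 if est == 0 else float("inf"))
    p = float(fit.pvalues[1]) if se > 0 else (1.0 if est == 0 else 0.0)
    return ContrastResult(est, se if np.isfinite(se) else 0.0, float(stat), p,
                          n_inland, n_coastal, method)
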