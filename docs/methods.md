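# Methods

## Synthetic microclimate

The temperature model is the classical harmonic solution of heat
conduction in a homogeneous half-space:

    T(z, t) = T̄ + w·(year − year₀)
              + A_ann · e^(−z/d_ann) · sin(ω_ann t + φ − z/d_ann)
              + A_diu(t) · e^(−z/d_diu) · sin(ω_diu t − z/d_diu)
              + ε(z, t)

with depth z (m), annual and diurnal angular frequencies ω (the annual
cycle uses a 365.25-day period), damping depths d (m), and a linear
warming trend w applied as a step at each calendar-year boundary (so the
noise-free annual mean increases by exactly w per year).  Time runs
hourly in UTC; leap days are included; the year boundary is Jan 1 00:00.

The weather noise ε is an AR(1) process generated once per site at the
surface and attenuated with depth by `e^(−z/s)` with e-folding depth `s`
(`noise_depth_scale`).  All levels of a site share one innovation
stream, so soil layers are vertically correlated the way real profiles
are.  The air level is the surface solution plus a constant offset with
unattenuated noise.

The diurnal amplitude may vary seasonally:
`A_diu(t) = A_diu + A_diu,seas · sin(ω_ann t + φ)`, peaking with the
seasonal maximum.  This represents the continental pattern of a much
larger diurnal range in summer than winter.  It matters mechanistically:
the hibernaculum tracks the *daily-mean* seasonal cycle (amplitude
A_ann, damped), while ground frost tracks the *daily-minimum* cycle
(amplitude A_ann − A_diu,seas at the surface).  With no modulation the
damped subsurface cue always advances faster under warming than the
surface frost margin retreats — every site is weakly trap-prone.
Seasonal modulation of the diurnal range flattens the daily-minimum
cycle and lets frost deplete faster than the cue advances, which is the
inland (no-trap) regime.

### Parameters and defaults

| parameter | unit | default | meaning |
| --- | --- | --- | --- |
| `mean_temp` | °C | 9.0 | annual mean at the surface |
| `annual_amplitude` | °C | 6.0 | seasonal half-range at the surface |
| `diurnal_amplitude` | °C | 3.0 | mean diurnal half-range |
| `diurnal_amplitude_seasonal` | °C | 0.0 | seasonal modulation of the diurnal half-range |
| `annual_phase` | rad | −1.906 | places the seasonal minimum near Jan 20 |
| `damping_depth_annual` | m | 2.0 | e-folding depth of the annual wave (moist soil) |
| `damping_depth_diurnal` | m | 0.12 | e-folding depth of the diurnal wave |
| `warming_rate` | °C/yr | 0.04 | linear inter-annual trend |
| `noise_sd` | °C | 1.5 | innovation SD of the surface AR(1) noise |
| `noise_ar1` | — | 0.85 | hourly autocorrelation (≈ 6 h e-folding memory) |
| `noise_depth_scale` | m | 0.15 | e-folding depth of noise attenuation |
| `air_offset` | °C | −0.5 | air minus surface mean difference |

### Scenario presets

Presets are frozen documented constants chosen to realize the two
qualitative regimes at desk scale; they are not fitted to, and make no
claim about, any real region.

* **coastal** (maritime, trap-prone): mean 8.2 °C, annual amplitude
  4.5 °C, diurnal 3.0 °C with no seasonal modulation, noise SD 1.5 °C.
  Low seasonality makes the degree-hour ramp shallow, so the fixed
  warming shift advances emergence by many days per decade, while
  marginal frost is spread thinly across the whole spring and depletes
  slowly: post-emergence frost exposure trends upward.
* **inland** (continental, not trap-prone): mean 7.2 °C, annual
  amplitude 7.0 °C, diurnal 5.0 °C with 4.5 °C seasonal modulation
  (winter diurnal range ~0.5 °C, summer ~9.5 °C), noise SD 1.5 °C.
  Steep seasonality pins emergence timing (small advancement) and the
  flattened daily-minimum cycle leaves a long marginal frost tail that
  warming erodes quickly: post-emergence exposure trends downward.

Under the default warming of 0.04 °C/yr over 35 years, the coastal
preset's post-emergence frost trend is ≈ +1.7 h/yr and the inland
preset's ≈ −0.4 h/yr (single site; sign stable across weather seeds).

## Degree-hours and windows

Degree-hours accumulate linearly above a 7 °C base — the approximate
critical minimum temperature below which viper locomotion is impaired —
on the hibernaculum trace, defined as the element-wise mean of the 10 cm
and 50 cm soil series (the depth band where overwintering animals are
most temperature-sensitive).  Accumulation restarts every Jan 1 00:00.
The cumulative value at an instant t covers all complete hours strictly
before t, so the value at midnight of a date is the accumulation through
the end of the previous day; this is the value attached to a sighting
date.  Per-depth accumulation is also available.

Windows: sightings and the emergence search run Jan 1–May 31; frost
accounting runs Jan 1 through June 30 (a May 31 end is a config option).
Frost comparison is inclusive (≤ 0 °C); the emergence hour itself counts
toward post-emergence exposure.

## Sighting generator

Each record is a site and a date: the ground-truth emergence date under
a known cue and threshold plus a non-negative reporting lag (zero,
uniform or exponential, in days), clamped to the recording window.
Because records carry dates rather than hours, ground truth is defined
at day resolution — an animal counts as emerged from the first day whose
00:00 accumulation already satisfies the cue.  This makes zero-lag
calibration an upper bound that is exact whenever the threshold is
attainable at a day boundary, and guarantees that lagged calibration
bounds the generating threshold from above.  Per-year record counts may
vary (including zero-record gap years).  Sightings are assigned to sites
uniformly at random; site-years where the cue never fires emit no
records and are logged.

Default study conditions: 35 years (1983–2017), 10 records per year,
uniform(0, 10 d) reporting lag, true accumulated-degree-hour trigger of
21 °C·h.

## Calibration and prediction

The threshold is the empirical quantile of sighting degree-hour values
at the configured percentile, using linear interpolation between order
statistics (the "type 7" convention, numpy's default) — fixed and
documented because different quantile rules move the threshold by more
than the quantities under study.  Calibration pools all sightings across
sites and years into one global threshold; sensitivity runs use the
2.5th and 10th percentiles.

Gradient collapse compares *daily means* of the 10 cm and 50 cm traces,
because brief daytime reversals of the near-surface profile occur even
in mid-winter; a raw-hour comparison is exposed as an option.  The
sharp-rise and air-temperature cues use 240-hour windows by default;
both windows are free parameters with no canonical value.

## Trend estimation

Pooled trends: linear mixed model with year (centred) as fixed effect
and a random intercept per site, fit by REML, Wald z test on the slope.
When the variance-components fit fails or degenerates (e.g. zero
residual variance on noise-free panels), the estimator falls back to
within-site centred OLS, which is algebraically identical for balanced
panels; the method used is recorded in every result.  Site trends are
ordinary least squares against year, requiring ≥ 3 years of data.

Trap rule: emergence slope < 0 with p < 0.05, and post-emergence frost
slope > 0 (sign only by default; a significance requirement on the
frost slope is a config switch).  No multiple-testing correction is
applied across sites; flag counts are nominal-level counts.  The
coastal/inland contrast is reported as the difference in mean
post-emergence frost hours (inland − coastal) from a linear regression
on the inland indicator; a logistic variant on the binarized any-frost
outcome is available, since a count response can reasonably be analysed
either way.

## Problem sizes

The default study and the acceptance script use 20 sites × 35 years of
hourly data at three levels (plus air when the air cue is active), which
runs in seconds; the test suite uses smaller fixtures throughout.  The
pipeline holds one study in memory (~10⁷ hourly values at the default
size) and streams nothing to disk except stage outputs.

## What the synthetic data does and does not show

The generator reproduces exactly the statistical features the analysis
consumes: depth-damped amplitude and phase lag, seasonality contrasts,
autocorrelated weather, a warming trend, and lagged opportunistic
sampling.  Passing tests therefore demonstrate that the inference chain
recovers known inputs and mechanisms under those conditions.  The
synthetic climate has no radiation, wind, soil-moisture or terrain
physics, no spatial correlation between sites, no observer effort
gradients, and its presets are not calibrated to any real region — so
absolute values (frost-hour totals, trap counts, contrast magnitudes)
are scenario properties, not predictions about real landscapes.
Real-data headline values from any particular study region are likewise
not reproducible from synthetic data and are not targets of the test
suite.

## Numerical notes

* Hourly timestamps are tz-naive UTC; each timestamp labels the start of
  its hour.
* Empirical quantiles: numpy `method="linear"`.
* First-crossing scans are exact vector scans (no interpolation within
  the hour).
* Sharp-rise ties break to the earliest interval; argmax on the gain
  vector guarantees this.
* Degenerate regressions (zero residual variance) report SE 0 with a
  p-value of 0 for a non-zero slope and 1 otherwise.
* All randomness flows from user seeds through `numpy.random.Generator`
  seed sequences; site identity enters via CRC32 so site streams are
  stable under reordering.
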