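# phenotrap

Spring-emergence phenology and post-emergence ground-frost exposure for
hibernating ectotherms, with detection of "climate trap" sites.

## The problem

Temperate reptiles and amphibians overwinter underground and time their
spring emergence from temperature cues in the soil around them.  Under
climate warming those cues fire earlier, but the risk of ground frost
above ground does not retreat at the same rate: at some sites, earlier
emergence *increases* exposure to post-emergence frost even though frost
is becoming rarer overall.  Sites where phenological advancement outpaces
within-season frost depletion are climate traps — the cue has decoupled
from the condition it evolved to predict.

`phenotrap` implements the full inference chain for this question as a
tested pipeline:

1. **Degree-hour accumulation.**  Hourly hibernaculum temperature
   (the mean of the 10 cm and 50 cm soil traces) is accumulated above a
   base of 7 °C: `DH(t) = Σ_h max(T_h − 7, 0) · 1 h`, restarting each
   Jan 1.
2. **Threshold calibration from occurrence records.**  Opportunistic
   sightings happen at an unknown lag *after* true emergence, so the
   emergence trigger is calibrated as a low percentile (default the 5th,
   type-7 interpolation) of the accumulated degree-hours observed at
   sighting dates, pooled across sites and years.  Alternative cues
   (sharp rise in accumulation, soil temperature-gradient collapse,
   10 °C rolling-mean air temperature) are implemented behind the same
   interface.
3. **Per-site-year prediction.**  Emergence is the first hour the
   cumulative degree-hours reach the threshold within the Jan 1–May 31
   search window.
4. **Frost exposure.**  Ground frost is any hour with surface
   temperature ≤ 0 °C; post-emergence exposure counts frost hours from
   the predicted emergence hour to the end of June.
5. **Trends and trap classification.**  Pooled trends use a linear mixed
   model (year fixed effect, site random intercept); site trends use OLS.
   A site is a trap candidate when its emergence trend is significantly
   negative while its post-emergence frost trend is positive.  Emergence
   timing and frost exposure are related by Pearson correlation, and
   inland/coastal sites (3 km coastline rule) are contrasted.

Because the original study's climate and occurrence data are proprietary,
the package ships a first-class synthetic microclimate module: the
analytic harmonic solution of soil heat conduction (depth-damped
amplitude `e^(−z/d)`, phase lag `z/d`) plus AR(1) weather noise shared
across depths, a linear warming trend, and a sighting generator with
known ground truth.  Coastal (low seasonality) and inland (high
seasonality) presets reproduce the trap and no-trap regimes.

## Worked example

```python
import phenotrap as pt

cfg = pt.StudyConfig(scenario="mixed", n_sites=20, years=(1983, 2017),
                     seed=1, out_dir="study_out")
result = pt.run_pipeline(cfg)
print(result.summary)
```

prints (seed 1):

```
{'n_sites': 20, 'n_sightings': 350,
 'threshold_dh': 21.916,
 'emergence_trend_days_per_year': -1.029,
 'spring_frost_trend_h_per_year': -7.232,
 'post_emergence_frost_trend_h_per_year': 0.526,
 'emergence_frost_r': -0.612,
 'n_trap_sites': 10,
 'coastal_contrast_h': -2.754}
```

Reading: the sighting generator used a true trigger of 21 °C·h and the
5th-percentile calibration recovered 21.9 °C·h from 350 lagged records.
Emergence advanced by about one day per year while overall spring frost
fell by ~7 h per year — yet pooled post-emergence frost *rose*
(+0.5 h/yr), emergence day and subsequent frost are negatively
correlated (r = −0.61; earlier emergence, more frost), and all 10
coastal sites are flagged as trap candidates while no inland site is.

The same pipeline is available from the shell:

```bash
phenotrap run-all --sites 20 --scenario mixed --seed 1 --out study_out
phenotrap simulate --sites 4 --years 1990:2010 --scenario coastal --seed 7 --out sim_out
phenotrap calibrate --sightings sim_out/sightings.csv --store sim_out/temperature_store.csv
```

Stage outputs (`sites.csv`, `sightings.csv`, `predictions.csv`,
`exposures.csv`, `trends.csv`, `traps.csv`, `site_map.csv`) and a
reproducibility manifest are written to the output directory; reruns of
the same config are byte-identical.

## Documentation

See `docs/methods.md` for the model, its assumptions, the meaning and
defaults of every tunable parameter, and known limitations of the
synthetic climate.
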