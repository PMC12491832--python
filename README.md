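# batphen

Individual-level hibernation phenology from RFID gate-logging data.

`batphen` re-implements, as a tested and reusable Python pipeline, the
analysis chain used to study how two sympatric bat species (*Myotis
daubentonii* and *M. nattereri*) shift their hibernation timing at a shared
hibernaculum: from raw two-reader RFID detection streams to per-individual
hibernation start/end/duration records, validation of the extraction
method, and linear mixed-model estimates of year trends and temperature
effects per species, sex and age class.  A synthetic-data generator
produces detection streams with known ground truth, so every stage — and
the statistical power of the whole design — can be checked end to end
without any field data.

It is intended for movement ecologists and phenology researchers working
with passive transponder (PIT/RFID) gate loggers at roosts, hibernacula or
nest boxes.

## The method

**Calendar conventions.**  A *bat year* runs 1 July–30 June (labelled by
the July year), so one winter is never split; a *bat day* runs noon to noon,
so one night's activity falls on one date.

**Pass reconstruction.**  Each entrance carries two readers ~20 cm apart;
the triggering order gives direction (outer→inner = entry, inner→outer =
exit).  Same-reader re-triggers within a burst window (default 5 s) are
collapsed; an inner and an outer hit within a pairing window (default 60 s)
form one directed pass; unpaired hits — and all single-reader-era hits —
become passes of unknown direction.

**Hibernation extraction.**  The hibernation bout of individual *i* in bat
year *t* is the *longest interval without a recorded pass* whose start bat
day falls between 1 July and 1 February and whose end bat day between
31 December and 30 April ("ecological hibernation").  In dual-reader mode
the interval must open with a confirmed entry and close with a confirmed
exit, otherwise the record is discarded.  Known power outages are handled
by masking (species × bat year × variable) combinations.

**Validation.**  The dual-reader era can be re-analysed as if only one
reader existed; the fraction of identical end dates between the two
analyses, and the fraction of *final departures* (first exit after the end
date with no re-entry within 24 h) within one week of the end date,
quantify how reliable the longest-gap proxy is.

**Trend models.**  Per species and response *y* ∈ {start, end, duration}
(start/end as day indices from 1 July):

    y ~ year_c * class + (1 | individual)          [days/year]
    y ~ temp_window * class + (1 | bat year)       [days/°C]

where `class` is the four-level sex–age factor (juveniles are promoted to
adult after their first bat year) and `temp_window` is the median hourly
air temperature of a species-specific 2-month climate window (Aug–Sep /
Feb–Mar for *M. daubentonii*; Nov–Dec / Jan–Feb for *M. nattereri*).
Models are fitted by REML (statsmodels `MixedLM`); the per-class *marginal
slope* is the covariate coefficient plus the class interaction contrast,
and the "overall" slope is the unweighted mean of the four class slopes,
with Wald standard errors throughout.

## Worked example

```python
from batphen import simulate as sim
from batphen.passes import build_passes
from batphen.extract import compile_dataset
from batphen.models import PhenologyTrendModel

cfg = sim.clean_config(seed=1, **sim.zero_temp_overrides())
weather, truth, captures, detections = sim.simulate_dataset(cfg)
table = compile_dataset(build_passes(detections), captures, mode="dual")
res = PhenologyTrendModel(table, "start", "daubentonii").fit()
print(res.summary())
print("change over 13 years:", round(res.project(13)["adult M"], 1), "days")
```

prints

```
Marginal start slopes [days/year] — daubentonii (n=5280, REML)
--------------------------------------------------------------
adult F        -0.871  se= 0.067  t= -12.91  p=4.13e-38
adult M        -2.154  se= 0.063  t= -33.96  p=9.49e-253
juvenile F     -0.586  se= 0.103  t=  -5.67  p=1.44e-08
juvenile M     -0.576  se= 0.105  t=  -5.47  p=4.55e-08
overall        -1.046  se= 0.049  t= -21.44  p=5.27e-102
change over 13 years: -28.0 days
```

The generator was configured with class entry trends of (−0.97, −2.14,
−0.70, −0.65) days/year for this species; the fitted marginal slopes
recover them within sampling error from ~5 300 extracted hibernation
records, and the adult-male start date advances by about four weeks over a
13-year span.  The same objects expose `slopes` (a tidy DataFrame),
`plot()` and the underlying statsmodels result.

The same pipeline is available from a shell:

```bash
batphen simulate config.yaml --outdir data/
batphen passes data/detections.csv --out data/passes.csv
batphen extract data/passes.csv data/captures.csv --mode dual --out data/phenology.csv
batphen fit-trends data/phenology.csv --out data/trends.csv
batphen fit-temperature data/phenology.csv data/weather.csv --out data/temp.csv
batphen validate-phenology data/detections.csv data/captures.csv
```

## File formats

Comma-separated UTF-8 with header rows and ISO-8601 timestamps (naive local
time):

| file | columns |
| --- | --- |
| detections | `timestamp, tag_id, entrance_id, reader` (`inner`/`outer`/`only`) |
| captures | `tag_id, species, sex, age_at_tagging, tagging_date, forearm_mm, mass_g` |
| weather | `timestamp, temp_c` (hourly) |
| phenology | one row per (tag, bat year): dates, day indices, duration, mode |

See `docs/methods.md` for modelling details, simulator assumptions and
known limitations.
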