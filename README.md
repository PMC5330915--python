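# coraldemog

Analysis pipeline for multiyear coral bleaching response-and-recovery
studies on tagged colonies of massive Caribbean reef-builders
(*Orbicella franksi*, *Stephanocoenia michelini*, *Siderastrea siderea*).
The package covers the three measurement layers such a study needs and a
synthetic-data generator that reproduces their statistical structure so
the whole pipeline is testable without field data.

## What it computes

**Thermal stress** (`coraldemog.thermal`). From depth-stratified
temperature-logger records: daily means, a monthly climatology whose
maximum (MMM) is the bleaching reference, the HotSpot anomaly
`HS(d) = max(0, T(d) − MMM)`, and Degree Heating Weeks

    DHW(d) = (1/7) · Σ { HS(j) : d − 84 < j ≤ d, HS(j) ≥ 1 °C }

in °C-weeks, with events flagged at HS ≥ 2.0 °C (stress) and DHW ≥ 4.0
°C-weeks (bleaching risk).

**Image quantification** (`coraldemog.imagequant`). Colony photographs
with an embedded color chart and scale marker: per-channel affine tint
calibration, CIELAB classification of colony pixels into pigmented /
partially bleached / bleached / dead, and planar areas in cm² with
bleached and partially bleached fractions of the live area. Dead patches
fully enclosed by live tissue are excluded from live area and reported
separately.

**Demography** (`coraldemog.demography`). Colony trajectories over the
observation schedule (months 0, 6, 9, 22, 34, 46, 58, 71, 89) partitioned
into response (0–9), recovery (22–58) and second-event (58–89) periods:
group live area as % of the month-0 baseline; annualized rates
`100·(e^{12β} − 1)` from the slope β of log-area on months (or from the
endpoint ratio); recovery time as the vertex of a quadratic fit with a
residual-bootstrap CI; compound-interest horizons
`ln(target/start)/ln(1 + r/100)`; and Student's t comparisons of bleaching
extent between colony size classes.

**Synthesis** (`coraldemog.synth`). Seeded generators for logger series
(seasonal + anomaly events + noise), colony tables (lognormal initial
sizes, per-period exponential growth with colony-level rate dispersion,
response-period mortality, loss to follow-up, multiplicative measurement
noise) and ground-truthed colony scenes. `PRESETS` holds the six
species × bleaching-group cells at the study's sample sizes and rates.

## Worked example

```python
from coraldemog import pipeline

pipeline.run_all(pipeline.RunConfig(out_dir="results/demo", seed=42))
```

writes a deterministic report bundle. From `thermal_events.json`, the
4-m depth channel of the default synthetic series crosses the 4 °C-weeks
risk threshold exactly twice:

    2005-09-18 .. 2005-12-13  peak DHW 8.8 °C-weeks
    2010-09-28 .. 2010-12-12  peak DHW 6.0 °C-weeks

`rates_report.json` for the bleached *O. franksi* group shows the
response-period collapse and its per-colony mean 9-month change:

    response rate  −40.7 %/yr (SE 6.3, n = 34 survivors, regression)
    mean change month 0→9: −25.6 % (SE 5.5)
    recovery vertex: t* = 33.1 months (r² = 0.67)

i.e. the group lost about a quarter of its live tissue per colony within
9 months of the bleaching event, and the quadratic fit of group relative
area turns back to growth around month 33. `live_area_table.csv` holds
the species × {All, Unbleached, Bleached} live-area table (cm² and % of
baseline at months 9, 58, 89), and `size_class_tests.csv` the large/small
bleaching-extent t tests — significant only for *S. siderea*, whose small
colonies bleach far more than its large ones.

The same stages are available from the shell:

```bash
coraldemog synth colonies --seed 2 --out colonies.csv
coraldemog demography --input colonies.csv --out-dir report/
coraldemog run-all --out-dir results/demo --seed 42
```

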