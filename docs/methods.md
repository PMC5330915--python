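# Methods

This note records the models, conventions and numerical choices behind
`coraldemog`, and what the synthetic-data generator does and does not
emulate.

## Thermal stress indices

Logger readings (15–40 °C accepted; outliers rejected as instrument
glitches) are averaged to daily means per depth channel. The climatology
pools daily means by calendar month over a configurable baseline year
range (default: the whole record); its maximum monthly mean (MMM) is the
HotSpot reference. The satellite-product convention uses twice-weekly
nighttime composites; with in-situ loggers we apply the same formulas to
daily means, which is the natural in-situ analogue and matches how such
records are plotted and summarized.

DHW uses the standard 84-day trailing window and a 1.0 °C accumulation
floor, both configurable. Days whose window extends before the record
start are flagged `dhw_incomplete`; days with more than 10% of the window
missing are flagged `dhw_gap_affected` (the sum is taken over available
days rather than interpolating). Events are maximal calendar-contiguous
runs over the thresholds (HotSpot ≥ 2.0 °C → `stress`; DHW ≥ 4.0 °C-weeks
→ `bleaching_risk`). Depth channels are fully independent — no vertical
interpolation.

## Image quantification

Calibration fits `true = gain·observed + offset` per channel over the
chart patches by least squares; a patch is usable when its pixel spread
is below 0.05 (occluded patches fail this) and at least three are
required. Classification happens in CIELAB after correction:

| class | rule | default |
|---|---|---|
| dead | a* below a green-turf cutoff | a* < −10 |
| bleached | high lightness, low chroma | L* ≥ 80 and C* ≤ 14 |
| partially bleached | intermediate lightness band | L* ≥ 55 |
| pigmented | otherwise inside the mask | — |

These thresholds are reproducible conventions standing in for the visual
"nearly completely white" vs "residual pigmentation" judgement; they are
carried in `ClassifierConfig` and echoed into output metadata. Live area
is (pigmented + partial + bleached) pixels × (cm/pixel)²; projected
planar area only, no rugosity correction. Dead components that touch
neither the image border nor background pixels are interior dead patches
(reported separately, never part of live area); dead regions on the
colony margin count toward the dead total. The colony mask can be
supplied (polygon or boolean array) or derived from background-color
distance; very large colonies can be measured on a sub-region with the
observation flagged `subsampled`.

## Demography

Analysis periods: response (months 0–9; observations 0, 6, 9), recovery
(22–58) and second-event response. The second-event period is anchored at
the month-58 observation (58, 71, 89) so its rate measures change from
the pre-event area, with the two post-event observations as endpoints.

Rates are multiplicative. Regression on raw areas cannot produce a
well-defined annualized percent, so the regression estimator fits
log(area) on months and annualizes the slope, which agrees with the
endpoint estimator to machine precision on exponential trajectories and
is consistent with the compound-interest horizon arithmetic. Colonies
reaching zero area use the endpoint method (−100 %/yr) for that period.

Group rates average per-colony *log slopes* and annualize the mean
(a geometric mean of growth factors). Under lognormal colony-to-colony
rate dispersion — which the measured SEs imply — the arithmetic mean of
per-colony percent rates is biased upward by `e^{σ²/2}`; the geometric
aggregate is unbiased for the generating rate. The arithmetic variant
remains available (`aggregate="arithmetic"`), as does Welch's t test next
to the default pooled-variance Student's t.

Response-period group loss is the mean per-colony % change between
months 0 and 9 over colonies alive at month 9. Whole-colony mortality is
reported separately, which is the convention that makes the printed group
rates, mortality counts and mean losses mutually consistent; an
`include_dead` flag includes deaths as −100% if desired. Lost-to-follow-up
colonies leave every statistic from their first missing observation
onward. Size classes split at the species mean month-0 area, ties going
small (deterministic).

Recovery time fits `a·t² + b·t + c` and reports the vertex `−b/2a` with
r²; curvature below 1e-12 (months and values normalized to unit scale)
yields a no-vertex result, and vertices outside the observed span are
flagged extrapolated. The bootstrap CI resamples fit residuals
(400 draws, percentile interval). Horizons use
`ln(target/start)/ln(1+r/100)` and are reported unreachable when the rate
sign points away from the target. Reported percentages round to 2
decimals and rates to 1; full precision is kept internally.

## Synthetic generator

`simulate_temperature` — sinusoidal seasonality (mean 28.68 °C, amplitude
1.5 °C, peak near mid-September) with triangular anomaly ramps, by
default one in 2005 (2.2 °C × 100 d) and a lesser one in 2010
(1.9 °C × 90 d), sized to carry DHW past 4 °C-weeks in exactly those two
years at every depth; Gaussian reading noise (0.15 °C), slight cooling
and anomaly damping with depth.

`simulate_colonies` — per colony: lognormal initial area (parameterized
by the arithmetic mean, since the calibration inputs are group totals
divided by n); per period a monthly log slope
`[ln(1+r/100) + N(0, σ_period)]/12`, so the specified rate is the
expectation of the log slope; exact response-period death counts (area 0
from month 6 or 9); loss to follow-up from a random later observation;
lognormal measurement noise (CV 5%, matching the inherent variance of
photographic planar-area re-measurement) on every emitted area. Initial
bleached/partial extents are drawn from the per-group means and SDs, decay
with time constants of 2 and 9 months, and for *S. siderea* are
conditioned on colony size (large colonies barely bleach), which is what
drives the size-class t test.

Preset calibration: sample sizes, mortality counts, and per-period rates
are the study's printed values where printed. Colony-level rate
dispersions are back-solved from printed SE·√n on the 9-month loss scale
(σ ≈ 0.56, 0.73, 0.29 per year for the three bleached response periods).
Rates not printed are back-solved from the group live-area table
(*S. michelini* unbleached: −12.2 response, −5.3 recovery %/yr) or set to
the described behaviour (*S. siderea*: −17.3 bleached response so the
expected per-colony loss equals the reported 11.2%; −2.0 unbleached
response per the "<1% in the first six months" description). These are
approximations: the underlying per-colony dispersion was never published.

`render_scene` — boundary-perturbed ellipse colony; dead fraction as an
interior hole (centre-most pixels), live classes as angular sectors with
pixel counts matching the requested fractions exactly up to rounding;
six-patch chart, 10-cm scale bar, multiplicative water tint, additive
pixel noise.

**What passing tests do not show.** The generator emulates the study's
statistical structure, not reef imagery or hydrography: colony scenes are
flat cartoons (no lighting gradients, parallax, or partial occlusion), so
segmentation accuracy here bounds nothing about field photographs; colony
dynamics are piecewise-exponential with independent lognormal deviations,
so period boundaries are sharp and there is no spatial or temporal
autocorrelation; and because per-colony rates are median-parameterized,
group *totals* drift above the median trajectory over long periods
(a Jensen effect of the rate dispersion), so synthetic group-total tables
are only calibrated to the study's printed totals at the baseline and the
9-month observation, not at later months.

## Problem sizes

Default test and reproduction runs use the study's own sample sizes
(n = 37/15, 62/6, 25/33 colonies; 9 observations each), 16-year
temperature records at 3 depths with 4 readings/day, 100-replicate
coverage checks with 400 bootstrap draws, and 480×360 rendered scenes.
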