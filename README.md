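# firescape

Gridded fire-susceptibility analysis and matched estimation of the effect
of protected-area status on fire occurrence.

The package implements a two-part workflow on a harmonized 1-km
equal-area analysis grid:

1. **Frequency-ratio susceptibility mapping.** Each causative factor
   (tree cover, land cover, elevation, slope, aspect, fire-season
   temperature, population density, travel time, distance to roads and
   to the forest edge) is divided into class intervals; per class the
   frequency ratio FR = (fire share of class) / (cell share of class)
   is computed, stratified by protection status. Per cell, the Fire
   Susceptibility Index (FSI) is the sum of the cell's class FRs over
   all factors, and dominant causative factors within high-FSI pixels
   are ranked by mean FR.
2. **Mahalanobis-distance matching.** Treating protection as a binary
   treatment and fire presence as the outcome, each protected cell is
   matched with replacement to the nearest non-protected cell under the
   Mahalanobis metric (pooled covariance), with a per-covariate 1-SD
   caliper. Outputs: the ATT with an Abadie–Imbens style standard
   error, a before/after balance table (means and variance ratios) and
   a covariate correlation screen at |r| ≥ 0.95.

A seeded synthetic-landscape generator produces spatially
autocorrelated covariate stacks, a confounded protection mask and
Bernoulli fire occurrences with closed-form ground truth (including the
true ATT), so every stage is testable without the real raster archive.

## Command line

```bash
# synthetic landscape: rasters + MCD14ML-dialect fire CSV + truth JSON
firescape simulate --seed 1 --out sim/

# full pipeline into a report bundle
firescape run-all --seed 1 --out bundle/
```

The bundle contains `fr_protected.csv`, `fr_nonprotected.csv`,
`fsi.tif`, `ranking.csv`, `balance.csv`, `effect.json`, `units.csv`,
`correlation.csv` and a JSON-lines `run_log.jsonl` with stage timings
and cell accounting. Individual stages are exposed as `simulate`,
`harmonize`, `fr`, `fsi`, `rank`, `match` and `report` subcommands; see
`firescape <cmd> --help`.

### Real-data mode

Rasters are single-band TIFF (float32 continuous, int16 categorical,
uint8 binary) with the grid geometry and nodata sentinel stored in the
TIFF description tag. The analysis grid is an abstract equal-area grid:
reprojecting source data to a common equal-area CRS and expressing
coordinates in km is a preprocessing responsibility. Active-fire CSVs
use the MCD14ML column dialect (`latitude, longitude, brightness, scan,
track, acq_date, acq_time, satellite, confidence, version`); only
latitude/longitude/confidence are interpreted, and a synthetic dialect
with explicit `x_km`/`y_km` columns is also accepted. Detections with
confidence below 95 are dropped by default.

## Conventions

- Majority-filter ties resolve to the lowest category code.
- Cubic convolution uses the Keys kernel (a = −0.5) with edge clamping.
- Slope/aspect by Horn's method; aspect is the compass bearing of
  steepest descent, flat cells carry the sentinel −1.
- Continuous classing is left-closed/right-open with the top edge
  closed; values outside the breakpoints become nodata.
- Complete-case analysis: a cell with nodata in any covariate is
  excluded from all downstream statistics.
- Matching units are 1-km cells; spatial autocorrelation between units
  is not modelled.
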