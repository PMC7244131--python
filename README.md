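# cropsuit

Fuzzy-set crop habitat suitability modeling: trapezoidal membership scoring of
environmental criteria, law-of-the-minimum combination, per-pixel raster
evaluation, producer-site validation statistics, and climate-model ensemble
projection with area/change summaries.

The package evaluates a crop's niche from five criteria — mean annual
temperature (°C), annual rainfall (mm/yr), solar radiation (W/m²), soil pH,
and soil drainage class (ordinal 1–7). Each criterion maps to a 0–100 score
through a trapezoidal fuzzy set (absolute range → 0, optimal range → 100,
linear ramps between), and the overall score is the minimum across criteria
(the most limiting factor governs). Two breadfruit parameterizations ship as
built-in profiles: `breadfruit_final` (refined) and `breadfruit_ecocrop`
(EcoCrop database defaults).

## Modules

| Module | Purpose |
|---|---|
| `cropsuit.fuzzy` | `FuzzySet`, `CropProfile`, `membership`, `combine_min`, `score_record` |
| `cropsuit.profiles` | YAML profile (de)serialization and the two built-in profiles |
| `cropsuit.raster` | `GridLayer`/`LayerStack`, alignment checks, `suitability_map`, spherical `cell_areas`, GeoTIFF I/O |
| `cropsuit.validation` | Producer sites, criterion masking (irrigation → drop rainfall, amendment → drop pH), RMSE / Nash–Sutcliffe ME / RSR / Willmott IA / OLS, grouped reports |
| `cropsuit.projection` | `ScenarioEnsemble` mean suitability, change maps, score-bin `AreaTable`s (million km²), percent change, categorical crosstabs |
| `cropsuit.synth` | Seeded synthetic inputs: gradient climates, patchy soils, perturbed ensembles, noisy producer sites, reference class maps |
| `cropsuit.cli` | `cropsuit` command-line pipeline |

Rasters are single-band GeoTIFFs (read/written via `tifffile` with standard
GeoTIFF tags); layers must share grid, transform, and CRS kind — no implicit
resampling. Nodata (default sentinel −9999) in any used layer propagates to
the output. Geographic cell areas use the exact spherical band formula, so a
full global grid sums to 4πR².

## CLI

```sh
# generate a synthetic testbed (rasters + sites CSV + optional ensemble/reference)
cropsuit synth --seed 7 --ensemble --reference --out-dir fixtures/

# evaluate a profile over criterion rasters
cropsuit suitability --profile breadfruit_final \
    -l temperature=fixtures/temperature.tif -l rainfall=fixtures/rainfall.tif \
    -l solar_radiation=fixtures/solar_radiation.tif -l soil_ph=fixtures/soil_ph.tif \
    -l drainage_class=fixtures/drainage_class.tif --out suit.tif

# validate against measured producer productivity
cropsuit validate --profile breadfruit_final --sites fixtures/sites.csv --out report.csv

# ensemble projection: baseline + N members -> mean map, change raster, area tables
cropsuit project --profile breadfruit_final -b temperature=... -b rainfall=... \
    -b solar_radiation=... -b soil_ph=... -b drainage_class=... \
    --member temperature=m0_t.tif,rainfall=m0_r.tif --member ... --out-dir proj/

# area binning and categorical comparison
cropsuit bin-areas --map suit.tif --out areas.csv
cropsuit compare --reference fixtures/reference_classes.tif --map suit.tif --out crosstab.csv
```

Logs go to stderr; results go to files. Each run writes a
`*.manifest.json` (config echo, profile thresholds, seed, version) sufficient
to reproduce it. Exit codes: 0 success, 1 input error, 2 internal error.

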