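# gridbias

Does the choice of map projection bias species distribution models?
`gridbias` builds a synthetic world with a *known* species–climate
relationship, grids it onto the two classic analysis grids — a 1° long-lat
grid (cell ground area shrinking toward the poles) and a 100 km equal-area
Mollweide grid — fits six weighted binomial GLM variants, and measures how
far each variant's coefficients drift from the equal-area, land-cover-
weighted reference in units of its standard errors.

## The six model variants

| projection | cell-area weight | land-cover weight | abbreviation |
|-----------|------------------|-------------------|--------------|
| long-lat  | –                | –                 | L            |
| long-lat  | yes              | –                 | LA           |
| long-lat  | –                | yes               | LL           |
| long-lat  | yes              | yes               | LLA          |
| equal-area| –                | –                 | M            |
| equal-area| –                | yes               | ML (reference) |

Per non-reference variant *D* and coefficient *i* the relative bias is
`delta_i = |beta_i(D) - beta_i(ML)| / se_i(ML)`; per species these are
averaged into one `mean_delta` per variant, weighting each predictor's
linear and quadratic term by that predictor's partial explained deviance.

## Package layout

- `gridbias.projection` — spherical geodesy: native Mollweide forward /
  inverse transforms (Newton with bisection fallback for the auxiliary
  angle), long-lat cell areas, degree-of-longitude lengths.
- `gridbias.world` — the synthetic planet: seeded land mask (thresholded
  harmonic field), four latitudinally structured climate surfaces with
  controlled collinearity (max VIF ≈ 2), and virtual species defined by a
  logistic niche (linear + quadratic terms on standardized predictors,
  optional smooth nuisance component and coast-avoidance term).
- `gridbias.gridding` — analysis grids, fine-to-coarse aggregation
  (area-split assignment; land-masked predictor means; coverage-fraction
  presence thresholding at >10%), and the three regression weights.
- `gridbias.sdm` — weighted binomial GLM fitting (statsmodels backend),
  post-fit coefficient standardization, partial explained deviance,
  McFadden pseudo-R², VIF, prediction.
- `gridbias.experiment` — the pipeline head: run all variants per species,
  bias statistics vs the ML reference, expected / thresholded range areas,
  cross-species summary with a blocked two-way ANOVA and Tukey-HSD variant
  contrasts.

## CLI

```sh
# spot-check the geodesy
gridbias proj forward 37.3 61.8
gridbias proj degree-length 45

# full pipeline, stage by stage
gridbias simulate --config config.json --seed 3 --outdir world/
gridbias gridify  --world world/ --projection equalarea --out cells_ea.csv
gridbias gridify  --world world/ --projection longlat   --out cells_ll.csv
gridbias fit  --cells cells_ea.csv --variant ML --out ref.json
gridbias fit  --cells cells_ll.csv --variant L  --out L.json
gridbias bias --fit L.json --ref ref.json --out bias.json

# or everything at once (12 default virtual species, all six variants)
gridbias run-all --seed 1 --outdir out/
gridbias summarize --indir out/
```

`run-all` writes tidy `fits.csv`, `bias.csv`, `ranges.csv`, `species.csv`,
per-grid `cells_<grid>.csv` tables and a `manifest.json` (seed, config
hash, library versions). Configs are YAML or JSON; see
`tests/test_cli.py` for the schema.

## Conventions

- Sphere of radius 6371 km for areas; the WGS84 equatorial radius
  (6378.137 km) only for the quoted degree-of-longitude lengths.
- Longitudes live in [-180, 180); grid cells are identified by their
  lower-left corner with half-open [low, high) intervals; the equal-area
  grid is anchored at the Mollweide origin.
- Everything stochastic flows from integer seeds; identical configurations
  reproduce outputs bit for bit.
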