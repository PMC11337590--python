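# equicatch

Modelled service areas and equity statistics for emergency-medical
resources. Given a table of small-area geography units (centroid,
population, area, deprivation decile) and a table of resource base
locations, `equicatch`:

1. assigns every unit to its nearest resource (great-circle distance or
   a user-supplied travel-cost matrix), constrained within nation by
   default;
2. aggregates each catchment into per-resource totals — population,
   area (km²), and median deprivation decile;
3. fits univariate and multivariate log-linear regressions of catchment
   population on median decile and log area, reporting coefficients
   with t-based 95% CIs, p-values, adjusted R², F statistics, and the
   percent-change reading of each coefficient;
4. runs a Spearman rank-correlation sensitivity analysis; and
5. classifies catchments into a 3×3 bivariate (population × deprivation)
   tercile scheme for choropleth mapping.

A synthetic-data module generates multi-nation geographies with
balanced within-nation deprivation deciles, spatially autocorrelated
deprivation, and a configurable true effect linking catchment median
decile to log catchment population — so the whole pipeline is testable
without any external download.

## CLI

```sh
# generate a synthetic geography
equicatch simulate --config sim.yaml -o data/

# individual stages
equicatch assign --units data/units.csv --resources data/resources.csv -o assignment.csv
equicatch summarize --units data/units.csv --assignment assignment.csv \
    --resources data/resources.csv --colocated split -o summaries.csv
equicatch regress --summaries summaries.csv --model univariate -o result.json

# or the whole pipeline from a YAML config
equicatch run --config run.yaml
```

`run.yaml` keys: `units`, `resources`, `outdir` (required); `cost_matrix`,
`geometries`, `within_nation`, `colocated_strategy` (`split`|`share`),
`cost_units`, `weighted_median` (optional). The pipeline writes
`assignment.csv`, `summaries.csv`, `result.json`, `classes.csv`,
`catchments.geojson` (when geometries are given) and `run.log`.

`sim.yaml` example:

```yaml
seed: 7
nations:
  - {code: EN, n_units: 400, bbox: [-2.0, 51.0, 1.0, 54.0]}
  - {code: SC, n_units: 400, bbox: [-5.0, 55.0, -2.0, 58.0]}
n_resources_per_nation: 10
true_slope: -0.20
colocated_pairs: 2
```

Exit codes: 0 success, 2 validation/schema error, 3 configuration error.

## File formats

- Units CSV: `unit_id,nation,lon,lat,population,area_km2,imd_decile`
  (WGS84 degrees; decile 1 = most deprived).
- Resources CSV: `resource_id,base_id,name,nation,lon,lat` (two
  resources may share a `base_id` = co-located teams).
- Cost matrix CSV: `unit_id,<resource_id_1>,<resource_id_2>,...`.
- Geometries: GeoJSON FeatureCollection with feature property `unit_id`.

## Co-located teams

Two teams at one base have identical nearest-distance catchments. With
`--colocated split` (default) the shared catchment's population and area
are divided equally between the two analysis rows, conserving national
totals; with `share` both rows carry the full totals and are flagged.

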