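# carniplan

Population-status assessment and spatial conservation planning for large
carnivores, as a reusable, tested pipeline:

1. **Suitability post-processing** (`carniplan.suitability`) — spatial
   thinning of presence records (one per 144 km² cell), decision-threshold
   selection by maximum sensitivity + specificity, four-class
   reclassification (unsuitable / marginal / medium / high), and evaluation
   by AUC, omission rate and a one-sided binomial test.
2. **Occupancy mapping** (`carniplan.occupancy`) — suitable habitat split
   by roads into 4-connected fragments; fragments labelled occupied (AJO),
   potentially occupied (APJO) or empty using the median distance of
   outside records to the nearest fragment as the search radius.
3. **Abundance and density** (`carniplan.abundance`) — Bayesian spatially
   explicit capture–recapture (SECR) with data augmentation, fitted by
   Metropolis-within-Gibbs MCMC (half-normal detection, uniform activity
   centers over a discretized state space); a jackknife Mh + buffer-union
   effective-area fallback for surveys without spatial recaptures.
4. **Prioritization** (`carniplan.priority`) — single-linkage grouping of
   occupied fragments (<15 km), rule-based classification into JCU Type
   I/II, PJCU or small fragment (50-adult population/capacity threshold,
   230 km² good-habitat threshold), empty-area rating (expansion / future
   core), population aggregation and recommendation lookup.
5. **Connectivity** (`carniplan.connectivity`) — resistance as an inverse
   linear transform of suitability, cost-distance grids and pairwise
   least-cost linkages on the 8-neighbour cell graph.
6. **Synthetic data** (`carniplan.synth`) — autocorrelated suitability
   surfaces, roads, presence records and SECR capture histories with known
   ground truth, so every stage is testable offline.

Rasters are plain-text ESRI ASCII grids (`.asc`) in planar km coordinates;
vector data are GeoJSON; tables are CSV; reports are JSON.

## Command line

```sh
carniplan simulate --extent-km 60 --n-presences 200 --seed 1 --out-dir work/
carniplan classify-suitability --raster work/suitability.asc --records work/records.csv --out-dir work/
carniplan occupancy --classmap work/classmap.asc --records work/records.csv --roads work/roads.geojson --out-dir work/
carniplan fit-secr --traps traps.csv --detections det.csv --buffer-km 15 --seed 1 --out fit.json
carniplan prioritize                 # bundled unit-evidence table
carniplan connectivity --suitability work/suitability.asc --units units.geojson --out-dir work/
carniplan run-all --out-dir work/    # full synthetic pipeline, reproducible report
carniplan validate --suitability work/suitability.asc --records work/records.csv
```

`carniplan prioritize` (and `run-all`'s units-table mode) accepts a
unit-evidence CSV with columns `name, both_sexes, total_area_km2, ajo_km2,
apjo_km2, good_area_km2, pop, pop_lo, pop_hi`; a reference table is bundled
at `carniplan/data/priority_units.csv`.

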