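# fencekit

Rule-based modeling of fence locations and fence density across a landscape,
with a survey-based accuracy assessment. Given land-tenure parcels, roads and
land cover, the package predicts where fences stand, rasterises fence density,
and scores the model against (real or simulated) roadside GPS surveys using
buffered-point confusion matrices and Cohen's kappa.

The model is a fixed sequence of geoprocessing rules:

1. **Tenure fences** — BLM land is replaced by its pasture subdivisions;
   adjacent state (then Bureau of Reclamation, then Fish & Wildlife Service)
   parcels are fenced together; state inholdings surrounded by BLM dissolve
   into it; private/tribal parcels merge by owner and adjacency (small
   parcels also by shared mailing address), units larger than two sections
   (5.2 km²) stand alone and smaller ones dissolve into the neighbour closest
   to that size; National Park Service and Forest Service land is unfenced.
   The outlines of the resulting units are the tenure fences.
2. **Road fences** — primary and secondary roads (and local roads ≥ 1,200 m,
   plus shorter locals reachable from them through an iterative intersection
   search) carry fences built from flat-capped buffers (19 m / 11 m
   half-widths) whose square ends — segments of exactly 38 m / 22 m — are
   deleted so fences never bisect a road. Short fenced locals keep a single
   offset line on one side.
3. **Land-cover fences** — croplands are consolidated (non-crop inclusions
   ≤ ½ section absorbed into crop bodies ≥ 3 sections), fences are drawn
   between large croplands and native prairie larger than ½ section, and all
   tenure fencing inside large croplands is masked out.
4. **Synthesis & density** — the three sources are combined (road fences
   lying completely within 20 m of other fencing are suppressed; water
   bodies, study-area edge artefacts and exclusion areas are handled;
   externally provided fences are appended) and fence density is computed
   with a flat circular kernel (10 km search radius, 1.5 km cells) in km of
   fence per km², plus zonal statistics.
5. **Survey & accuracy** — stratified random 3.2 km roadside transects
   (habitat × pavement, ≥ 3.5 km apart), and three assessments against 30 m
   buffered points: roads-only, internal fencing (via fence-junction nodes),
   and total, each summarised by Cohen's kappa with an asymptotic 95% CI.

A first-class synthetic-landscape module generates checkerboard tenure,
classed road grids, crop/prairie mosaics, ground-truth fences (the model's
own output, optionally degraded by feature drop-out and vertex jitter) and
simulated GPS surveys, so everything runs end-to-end with no external data.

## CLI

```sh
fencekit simulate --out bundle --seed 1 --cols 10 --rows 10   # synthetic inputs
fencekit tenure --tenure bundle/tenure.geojson --pastures bundle/pastures.geojson \
    --out tenure_fences.geojson --report absorbed.csv
fencekit landcover --landcover bundle/landcover.geojson \
    --tenure-fences tenure_fences.geojson --out lc_fences.geojson \
    --masked-tenure-out masked_tenure.geojson
fencekit roads --roads bundle/roads.geojson --out road_fences.gpkg
fencekit synthesize --tenure-fences masked_tenure.geojson \
    --landcover-fences lc_fences.geojson --road-fences road_fences.gpkg \
    --study-area bundle/study_area.geojson --out fences.gpkg
fencekit density --fences fences.gpkg --study-area bundle/study_area.geojson \
    --out density.tif --zonal-out zonal.csv
fencekit assess --fences fences.gpkg --road-fences road_fences.gpkg \
    --transects bundle/transects.geojson \
    --survey-points bundle/survey_points.geojson --out report.json
```

Every numeric threshold lives in one YAML config (see
`fencekit.geo_core.ModelConfig`; pass `--config`), including the tenure-rule
ledger (`disabled_tenure_rules`).

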