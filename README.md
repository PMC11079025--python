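# landmdi

Pipeline for analysing land multi-degradation in agricultural landscapes.
Twelve degradation processes (water/wind erosion, soil organic carbon loss,
salinization, acidification, compaction, nutrient imbalances, pesticide and
heavy-metal pollution, vegetation degradation, groundwater decline, aridity)
are binarized into Critical / Non-critical layers by a documented rule
registry; their per-pixel co-occurrence count forms a Land Multi-degradation
Index (LMI) that is binned into degradation classes, reported per zone and
land-use stratum, decomposed into dominant process combinations, and wrapped
in a Monte-Carlo + Random-Forest uncertainty analysis of the rule thresholds.

A synthetic-data module generates every input (process rasters, annual trend
stacks, P/PET climatologies, a CLC-like land-use mask, a zone partition) with
known per-pixel ground truth, so the whole pipeline is testable without the
original continental datasets.

## Package layout

| module                 | contents |
|------------------------|----------|
| `landmdi.grid`         | `Grid` raster model, GeoTIFF I/O (via tifffile geo-tags), alignment, area accounting |
| `landmdi.synthetic`    | seeded scenario generator with planted criticality / class proportions |
| `landmdi.trends`       | pixel-wise Mann-Kendall test (tie-corrected, continuity-corrected) and Sen's slope |
| `landmdi.criticality`  | the 12-process rule registry and all composite classifiers |
| `landmdi.lmi`          | LMI computation, class binning, zonal reports, histogram, Jenks natural breaks |
| `landmdi.combos`       | per-class combination tables, top-k selection, display coarsening |
| `landmdi.uncertainty`  | threshold perturbation (Normal(t, t/10)), label simulation, RF class probabilities / OOB / importances |
| `landmdi.pipeline`     | end-to-end orchestration and scenario (de)serialization |
| `landmdi.cli`          | `landmdi` command-line interface |

## CLI

```bash
# generate a synthetic scenario (GeoTIFFs + manifest + ground truth)
landmdi generate --seed 1 --outdir scen/

# classify a scenario directory into criticality masks
landmdi classify --scenario scen/ --outdir masks/

# full chain with desk-scale settings
landmdi run-all --quick --seed 1 --outdir run/ --stratum both

# summarize a finished run
landmdi report --rundir run/
```

`run-all` writes criticality masks, LMI count/class grids per stratum, zonal
reports and combination tables (CSV, byte-stable across reruns), per-class
probability maps, RF importances, class-area error ranges, and a JSON run
manifest with seeds and thresholds. An optional YAML config (`--config`) can
override every scenario and uncertainty setting; thresholds live in the rule
registry and are treated as data throughout.

Full-scale uncertainty settings (20 000 simulations, 1000 trees, 20
repetitions) are available via config; the defaults are desk-scale
(2000 / 200 / 5).

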