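# soil2leaf

Soil-to-plant heavy-metal transfer analysis for orchard monitoring data:
pigment quantification, bioaccumulation indices, site-level inference,
multivariate structure discovery (PCA / HCA / LDA), PLS regression of leaf
traits on soil metals, and probabilistic Monte Carlo exceedance risk against
food-safety thresholds.

## What's inside

| Module | Purpose |
| --- | --- |
| `soil2leaf.core` | Long-format measurement data model, CSV I/O, site/grand summaries, significance codes |
| `soil2leaf.datasets` | Packaged per-site reference tables (leaf analytes and BAFs for 20 orchard sites) |
| `soil2leaf.synthetic` | Seeded generator for orchard datasets (log-normal soil metals, BAF-driven leaf metals, metal-stressed pigments) |
| `soil2leaf.pigments` | Chlorophyll a/b from two-wavelength methanol-extract absorbances |
| `soil2leaf.baf` | Per-tree bioaccumulation factors, site summaries, accumulator classification |
| `soil2leaf.stats` | Welch ANOVA, Games–Howell post hoc (own studentized-range quadrature), Pearson/Spearman correlation matrices |
| `soil2leaf.multivariate` | Covariance PCA with varimax, Ward/Euclidean agglomerative clustering, stepwise LDA (Wilks' lambda, F-to-enter) |
| `soil2leaf.pls` | NIPALS partial least squares regression with per-response R² |
| `soil2leaf.mcs` | Log-normal fitting, 10,000-draw simulations, exceedance probabilities with a closed-form oracle |
| `soil2leaf.pipeline` / `soil2leaf.cli` | End-to-end orchestration, manifest, markdown report, `soil2leaf` CLI |

## CLI

```sh
# synthetic dataset as a long CSV (site_id,tree_id,compartment,analyte,value,units)
soil2leaf simulate-data --seed 1 --out orchard.csv

# full pipeline on synthetic data, deterministic given --seed
soil2leaf all --seed 1 --outdir results/run1

# individual stages, optionally from a YAML config
soil2leaf summarize --config config.yaml
soil2leaf baf --outdir results/baf
soil2leaf stats --seed 1
soil2leaf multivariate --no-standardize
soil2leaf plsr
soil2leaf mcs --seed 1
soil2leaf report --seed 1 --outdir results/report
```

A YAML config can set the simulation design, stage lists, analyte subsets,
cluster count, PLSR components, Monte Carlo iterations and threshold sets;
every value has a sensible default (20 sites x 4 trees, 2 latent components,
k = 4 clusters, 10,000 iterations, Cd 0.1 / Pb 0.3 mg/kg DW limits).

Reruns with the same config and seed produce byte-identical output bundles;
`manifest.json` records the config hash and per-file SHA-256.

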