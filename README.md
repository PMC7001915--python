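# richworld

Modelling global species richness from environmental drivers — as a tested,
reusable pipeline exercised end-to-end on synthetic worlds with known
generative structure.

Global biodiversity analyses ask how much of the spatial pattern of species
richness (distinct species per grid cell) is explained by environmental
drivers: temperature, primary production, solar energy, depth/elevation and
biogeochemical constraints, each summarised by its central tendency,
variability and seasonal phenology. `richworld` implements that analysis for
macroecologists and biodiversity-informatics developers:

* **Synthetic worlds** (`richworld.synthetic`) — an equal-area grid with
  spatially autocorrelated driver fields (some as monthly series with 12- and
  6-month harmonics), species ranges derived from environmental niches, point
  occurrence records with counts spanning 1–1000, and a richness surface
  generated from a *known* driver→richness function plus noise, so every
  downstream stage can be validated against truth without downloading
  anything.
* **Occurrence screening** (`richworld.screening`) — a record-sufficiency
  statistic for marine point archives: for each species, resamples of size
  *n* are drawn and the species' latitudinal/thermal range (1st–99th
  percentile interval) re-estimated; the minimum sufficient *n* is the
  smallest subsample size whose interval captures the full-sample range in
  >95% of 1000 resamples. Species under a global record threshold (default
  41) are removed; rarefaction curves per 20° latitude bin (analytic
  hypergeometric or Monte-Carlo) diagnose residual sampling bias.
* **Feature engineering** (`richworld.features`) — intra-/inter-annual
  mean, sd, range and CV summaries; 1%/99% quantile truncation
  (elevation/depth exempt); 0–1 rescaling with stored transform provenance;
  and Morlet continuous-wavelet seasonal intensity (time-averaged,
  scale-rectified band power at the 6- and 12-month periods, computed
  per grid cell). The response is 0–1 scaled ln(richness + 1).
* **Richness network** (`richworld.ann`) — a feed-forward regression with 3
  hidden layers of 10 rectified-linear units, 0.2 inverted dropout, momentum
  SGD (0.9, batch 128), mean-squared-error loss, an 80/20 train/test split
  and 5-fold cross-validated hyperparameter selection. Implemented on numpy
  arrays; seeded runs are bit-reproducible.
* **Interpretation suite** (`richworld.interpretation`) — bootstrapped
  noise-perturbation variable importance (fresh network per rep on a random
  data subset; ΔR² when one feature is replaced by resampled noise),
  1- and 2-feature partial dependence with data-distribution averaging,
  loess curve ensembles (median + 95% quantile bands over 100 resamples of
  10 000 points), observed−predicted residual maps, 2° zonal profiles, and
  empirical semivariograms for residual spatial autocorrelation.
* **Pipeline** (`richworld.pipeline`, CLI `richworld`) — one YAML config
  drives generate → screen → featurize → fit → interpret, with terrestrial
  and marine domains modelled by two independent networks sharing a world,
  per-stage seeds derived by hashing the global seed, and a checksummed run
  manifest that is byte-identical across reruns.

## Worked example

```python
import numpy as np
from richworld import (
    AnnConfig, SyntheticWorldConfig, build_feature_table, evaluate, make_grid,
    partial_dependence, simulate_driver_fields, split_train_test, train_ann,
    true_richness_function,
)

config = SyntheticWorldConfig(seed=12, n_true_drivers=3, n_distractor_drivers=0,
                              noise_sd=0.0)
grid = make_grid((-60, 60, -180, 180), cell_km=250.0)   # ~7,000 cells
drivers = simulate_driver_fields(grid, config)
richness = true_richness_function(drivers, config)       # known truth
layers = {n: l for n, l in drivers.static_layers.items() if n != "elevation"}
table = build_feature_table(layers, richness, mask=grid.domain_mask(None))

split = split_train_test(table, 0.8, seed=0)
model = train_ann(table, AnnConfig(epochs=150, dropout=0.0, learning_rate=0.02,
                                   seed=1), split=split)
m = evaluate(model, table, "test")
print(f"test R2 = {m.r2:.3f}, RMSE = {m.rmse:.3f} (n = {m.n})")
```

prints

```
test R2 = 0.994, RMSE = 0.016 (n = 1408)
```

i.e. on a noiseless world whose richness is an additive function of three
drivers, the network recovers 99.4% of the response variance on held-out
cells, with a root-mean-square error of 0.016 on the 0–1 scaled ln(x+1)
response. A partial-dependence sweep
(`partial_dependence(model, table, "driver_01")`) then traces each driver's
additive component, and replacing a driver column with resampled noise in a
retrained ensemble (`permutation_importance`) quantifies its share of the
explained variance.

The same flow runs from the shell:

```bash
richworld run --config config.yaml --seed 1 --out run_dir
richworld train --table run_dir/features_ocean.csv --out model.json
richworld pdp --model model.json --table run_dir/features_ocean.csv \
    --vars driver_01 driver_02 --out pd.csv
```

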