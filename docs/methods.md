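# Methods

This note documents the models and procedures `richworld` implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate about real data.

## The analysis in one paragraph

Species richness per equal-area grid cell is modelled as a nonlinear
function of environmental drivers. Occurrence archives are first screened
for record sufficiency; driver layers and monthly series are condensed into
per-cell features (central tendency, variability, seasonal phenology
intensity), truncated, and 0–1 scaled; a small feed-forward network maps
the scaled features to 0–1 scaled ln(richness + 1); and the fitted model is
interrogated with bootstrapped variable importance, partial dependence,
residual maps, zonal profiles and semivariograms. Terrestrial and marine
domains are fitted by two independent networks sharing the world.

## Grid

A Lambert cylindrical equal-area grid (standard parallel at the equator):
`x = R·λ`, `y = R·sin φ`, Earth radius R = 6371 km, default cell side
50 km on the plane, so every cell covers the same surface area. Centroids
sit at cell midpoints; for the full globe centroid latitudes approach but
never reach ±90°. Semivariogram distances are computed on this plane
(cell units × cell size), consistent with the grid's construction.

## Synthetic worlds

The generator emulates the statistical shape of compiled global data, not
any particular satellite product:

* **Static driver fields** are Gaussian-kernel-smoothed white noise
  (kernel sd = the configured correlation length, default 5 cells;
  longitude wraps), min–max scaled to [0, 1]. Kernel smoothing was chosen
  over spectral synthesis for simplicity and O(cells) cost.
* **Monthly series** (default: temperature, production, insolation; 120
  months) are a smooth spatial base plus 12- and 6-month cosines with
  per-cell spatially smooth phases and white observation noise
  (sd 0.05). Default amplitudes: temperature (0.8, 0.1), production
  (0.5, 0.4), insolation (1.0, 0.0).
* **Masks**: the lowest half (by area) of the elevation field is ocean —
  a one-parameter "sea level" that lets terrestrial and marine pipelines
  run side by side.
* **Species ranges**: each species draws 2 niche drivers and an interval
  around the driver values at a random cell of its domain (half-width
  uniform on [0.08, 0.3]); its range is every domain cell satisfying all
  intervals; empty draws are retried up to 20 times.
* **Occurrences**: record counts are log-uniform on [1, 1000] (mirroring
  the screening domain 1 < n < 1000); cells are sampled uniformly over the
  range, positions jittered uniformly within the cell. Each record's
  thermal value is the temporal mean of the temperature series at its
  cell — a package convention; real archives attach measured or
  climatological temperatures in ways that vary by source.
* **Richness**: the true driver→richness function is additive (with
  optional pairwise product interactions) on the ln(x + 1) response scale
  — default three terms with weights 1.0/0.8/0.6 and linear/bump/quadratic
  shapes plus an intercept of 0.2 — with Gaussian noise (default
  sd 0.05) added on that scale, then mapped through expm1 so the richness
  layer is non-negative and right-skewed like real richness counts (an
  identity link is available). The downstream ln(x + 1) transform
  recovers the response exactly, which is what makes functional recovery
  measurable.

Every output is a pure function of (config, seed); per-stage generators
use fixed seed offsets so adding a stage never perturbs earlier draws.

## Record-sufficiency screening

A species' latitudinal or thermal range is its 1st–99th percentile
interval (linear interpolation between order statistics — stated because
several conventions exist). A subsample of size n *captures* the range
when its own 1st–99th percentile interval covers the full-sample interval
shrunk by 1% of its width (the tolerance avoids measure-zero endpoint
failures on continuous data). The minimum sufficient record count is the
smallest n whose capture rate over 1000 resamples (without replacement;
with-replacement available) exceeds 95%.

Choices worth noting:

* Resamples are seeded per (seed, n), making the minimum a deterministic
  function of the seed, independent of search order. The default search
  is an ascending scan with early stop — that *is* the definition of the
  minimum; a binary search (`search="binary"`) is available as a speedup
  and assumes the capture rate is monotone in n, which holds empirically
  away from the coverage threshold.
* Note the direction: the subsample interval must *cover* the (shrunk)
  global interval. The opposite containment direction is vacuous —
  subsample percentile intervals are stochastically narrower than the
  full-sample interval, so every species would pass at n = 2.
* The "±" spread reported with the median minimum sufficient count is the
  median absolute deviation.
* The global record-count filter (default 41) is a single cutoff applied
  to all species; it is configurable.

Rarefaction curves use the analytic hypergeometric expectation
`E[S(n)] = Σ_i (1 − C(N−N_i, n)/C(N, n))` (computed via log-gamma) or a
Monte-Carlo subsampler; latitude bins are half-open, 20° wide, and mirror
outward from the equator so the hemispheres are split (the polemost bin is
truncated at 90°).

## Feature engineering

* Intra-annual statistics see only the 12-month climatology (per-cell
  monthly means across years); inter-annual statistics act across annual
  means; `annual_sum` is the across-year mean of the 12-month sums.
  Standard deviations use ddof = 1. CV with |mean| < 1e-9 returns 0 with
  a logged warning.
* Quantile truncation clamps to the 1%/99% quantiles computed over the
  masked domain only (per-domain models are fitted separately);
  elevation/depth bypass truncation. Constant layers pass through with a
  logged note; constant features are dropped at table assembly because
  their 0–1 scaling is undefined.
* Wavelet seasonal intensity: complex Morlet mother wavelet with
  ω₀ = 6 (the standard choice), geometric scales at 12 sub-octaves, band
  = scales whose equivalent Fourier period lies within ±1 month of the
  target (6 or 12). Series are mean-removed per cell; times inside the
  cone of influence (e-folding distance of the wavelet envelope) are
  excluded from the time average; per-scale power is divided by its scale
  (spectral-bias rectification) so the 6- and 12-month intensities are
  comparable and power scales as amplitude². Correctness is defined
  against an FFT-periodogram oracle (dominant-period ordering agreement
  on two-tone series), not bit-level agreement with any particular
  wavelet implementation.
* The response is ln(richness + 1), then 0–1 scaled; all transform
  parameters (per-feature quantiles, min/max, response min/max) are
  stored so predictions can be mapped back to raw richness.

## The richness network

Architecture: input → 3 hidden layers × 10 rectified-linear units →
linear output. Training: mean-squared-error loss, plain momentum SGD
(momentum 0.9, batch 128, shuffled mini-batches), inverted dropout 0.2 on
hidden activations (inference is deterministic), 10 epochs by default.
Unstated-by-convention choices: learning rate 0.05 by default (stable for
this architecture on [0, 1] inputs at batch 128; sweepable via
cross-validation), fan-in-scaled uniform weight initialisation, no
adaptive optimisers. Cross-validation selects by minimum mean fold RMSE
with fold-RMSE variance as tie-breaker (both are reported so either
reading of "minimize RMSE variance" can be audited), then smaller model,
then candidate order.

**Benchmark configuration.** The function-recovery, importance-recovery
and partial-dependence benchmarks run the same 3×10 rectifier
architecture with the dropout regulariser off, a 0.02 learning rate and
epochs raised to convergence (60–250 depending on problem size). Dropout
is a regulariser against observation noise, not part of the function
approximator: with 0.2 dropout on 10-unit layers the train-time noise
caps held-out R² near 0.77 on a noiseless world regardless of epochs,
while the same architecture without it reaches R² ≥ 0.99 and, on noisy
worlds, sits within 0.01 of the noise-variance ceiling
1 − σ²/Var(y). Converged per-rep models also matter for importance:
under-trained networks leak weight onto distractor features, inflating
their ΔR² medians.

## Interpretation suite

* **Importance**: each rep draws a random subset (default 80% of rows),
  trains a fresh network on 80% of it, and measures held-out R²; one
  feature at a time is replaced by resampled noise — by default the
  feature's own values sampled with replacement, which breaks the
  association while preserving the marginal (uniform noise is a flag) —
  and ΔR² = baseline − perturbed recorded. Ranking is by median ΔR²,
  ties alphabetical. Whether perturbation happens on training or held-out
  rows, and the subset size, are unspecified conventions in the field;
  both knobs are exposed and recorded in the output.
* **Partial dependence** averages predictions over all data rows with the
  swept feature(s) pinned (so the remaining inputs co-vary as observed);
  mean-pinning is available for comparison. Coverage flags mark grid
  points supported by the marginal range (curves) or occupied joint
  histogram bins (surfaces).
* **Loess ensembles**: 100 resamples of 10 000 rows by default, lowess
  smoother with span 0.75 (statsmodels' locally linear smoother),
  evaluated on a fixed grid; pointwise median and 2.5%/97.5% quantiles.
* **Residuals** are observed − predicted on the scaled response
  (positive = underpredicted). Zonal profiles are means over half-open 2°
  latitude bins; because cells have equal area, the cell-weighted
  recombination of bin means equals the global mean exactly.
* **Semivariograms**: γ(h) = mean of ½(zᵢ−zⱼ)² over cell pairs binned by
  plane distance; exhaustive pairs up to 10⁶ (≈1400 cells), seeded random
  pair subsampling beyond; empty bins are reported, not errored.

## Pipeline

Stage seeds are the first 4 bytes of SHA-256(global_seed ":" stage), mod
2³¹. Screening applies to marine point records only; terrestrial richness
comes from stacked ranges (the response can also be the known
driver→richness function, the default for benchmark worlds). The manifest
records the config (minus the output location), per-stage seeds, package
version and SHA-256 checksums of every artifact; two runs with one seed
produce byte-identical manifests. Stages are deterministic functions of
the config, so a stage invoked alone rebuilds its cheap upstream state
and recomputes only itself.

## Benchmark problem sizes

Synthetic benchmarks are sized for a single CPU: ~20 000 cells for
function recovery, ~26 000 cells × 50 reps × 10 seeds for importance
recovery, a 20×20 grid for the exhaustive semivariogram oracle, and a
100×100-cell, 200-species world for the double-run pipeline
reproducibility check. The screening oracle check uses 20 species of
50–160 records at 10⁴ resamples.

## What the synthetic benchmarks do not show

The generator reproduces the *shape* of real inputs (0–1 drivers,
skewed ln-scaled richness, 6-/12-month seasonality, 1–1000 record counts)
but not their content: drivers are independent smoothed-noise fields with
no cross-correlation structure, climate gradients or coastline geometry;
species niches are axis-aligned boxes; sampling effort is spatially
uniform; and the true response is exactly additive on the log scale.
Passing the recovery benchmarks therefore shows the machinery is correct
and well-calibrated — not that a 3×10 network suffices for real
biodiversity data, where drivers are collinear, effort is biased and the
response surface is unknown. Known limitations: no vector (polygon) range
geometry; no taxonomic or duplicate-record cleaning; monthly series must
span whole years; the lowess smoother is locally linear rather than
locally quadratic.
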