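# Methods

This note records the statistical model, the numerical choices, and the
limits of what the test suite demonstrates.

## Design-based, model-assisted mapping

The population is a finite set of square analysis pixels (default side
23 m) tiling an area of interest, partitioned into contiguous blocks of
as-equal-as-possible size: N pixels in M blocks gives M−1 blocks of
⌈N/M⌉ and a remainder block (5449 pixels in 50 blocks → 49×109 + 1×108).
Pixels may be ineligible (non-forest); they stay in the table, are excluded
from every estimation step, and are written as nodata.

Three sampling designs are supported, identified automatically from the
block attribute:

* **SRSWoR** — every pixel carries its own block id; π_i = n/N.
* **OPSS** — one uniform draw per block; π_i = 1/N_h with N_h the
  *eligible* count of block h (partially ineligible blocks use the eligible
  count, since sampling is from eligible pixels).
* **SYS** — equal blocks sharing one uniformly drawn within-block position;
  π_i = 1/K. Detection requires a deterministic within-block ordering; we
  order row-major by (y descending, x ascending) of centroids.

A non-SRSWoR population in which any block carries zero or two or more
sampled pixels violates all supported designs and is rejected.

The per-pixel estimator is regression + inverse-distance-weighted
residuals, harmonized by a single global ratio to the Horvitz–Thompson
total (see README for the formulas). Conservation (Σ map = T̂) holds to
floating-point precision on every run and is asserted at 1e-9 relative.
Because a sampled pixel receives its own residual back (zero-distance IDW
convention), the pre-harmonization map interpolates the field observations
exactly.

Joint inclusion probabilities are never computed: the pipeline's
uncertainty comes entirely from the bootstrap, not from an analytic HT
variance.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `collinearity_r` | 0.95 | candidates with a higher-ranked partner above this pairwise correlation are pre-filtered |
| `max_predictors` | ⌊n/10⌋ | forward-selection cap; prevents overfitting n=50 samples with 30 candidates |
| `idw_power` | 2.0 | IDW exponent (dimensionless) |
| `idw_k` | all | IDW neighborhood; `None` uses every sampled pixel |
| `clamp` | on | negative pre-harmonization estimates are set to 0 (densities are non-negative) *before* harmonization, so conservation survives clamping |
| `coords_as_predictors` | off | centroid coordinates exist for the interpolator; they join the regression candidate pool only on request |
| `cloud_prob_threshold` | 50 | per-cell cloud-probability cutoff in [0,100] |
| `max_cloud_pct` | 20 | scene-level cloud-cover cutoff (%), strict `<` |
| `B` | 1000 | bootstrap replicates (the method's floor) |

The AIC is the Gaussian profile form n·log(RSS/n) + 2k with k the number
of mean parameters (intercept included); the additive constant is
irrelevant to selection. Forward search stops when no addition lowers the
criterion. A zero-variance response (which arises legitimately inside
bootstrap replicates drawn from a constant pseudo-population) skips
selection and falls back to the intercept-only model.

The medoid distance is the sum over bands of squared differences to the
per-band median of the valid observations — the standard medoid of the
compositing literature; the scenes are date-sorted so exact distance ties
resolve to the earliest acquisition. Ties that differ only in the last
floating-point bit of two arithmetically equivalent distances may resolve
to either scene; the composite is otherwise invariant to scene order.
Mixed-resolution bands are aggregated on their native grids by
centroid-inclusion means (or bilinear resampling at the analysis-pixel
centroid, `--resample bilinear`); both are exposed because field practice
varies between averaging and bilinear resampling. A pixel left with no
cloud-free observation keeps a missing predictor and fails validation
unless `gap_fill` imputes the across-pixel mean.

## Randomness and determinism

One root seed drives everything. Sample draws consume
`SeedSequence([seed, 0])`; bootstrap replicate b, attempt a (after
failures) consumes `SeedSequence([seed, b, a])`. Replicates are therefore
independent of execution order, and the error map is bit-identical for any
worker count — asserted in the tests. Failed replicates (e.g. a
non-positive raw map total, which makes the harmonization ratio undefined)
are redrawn with the next attempt stream; more than 5% failures abort.

## The synthetic world

`simulate_population` emulates the structure the estimator assumes:
predictors are unit-variance smooth random fields (Gaussian-kernel-smoothed
white noise, default range 5 pixels) mixed with 20% white noise; the truth
is an affine combination (default intercept 0.04 m³/m², coefficients
±0.01-scale) plus a spatially autocorrelated residual field (sd 0.008) plus
independent noise (sd 0.004), clamped at zero. Defaults put the mean around
0.04 m³/m² ≈ 400 m³/ha, the scale of a productive temperate forest, with
roughly half the residual variation spatially structured. A configurable
fraction of pixels is ineligible. The generator does **not** emulate real
Sentinel-2 radiometry, orbital revisit, terrain effects, or measurement
error in field volumes; passing tests demonstrate the estimator's
arithmetic and design properties, not map accuracy on real imagery.

`monte_carlo_rmse_oracle` measures the pipeline's true per-pixel RMSE by
repeatedly drawing real samples from the known truth and re-running the
full map construction — the independent yardstick for the bootstrap.

## Known limitations

* **The bootstrap under-reads the true error when the assisting model is
  incomplete.** The pseudo-population is the final map: its white-noise
  component is zero (noise cannot be interpolated) and its residual surface
  is one IDW smoothing pass ahead of the truth. Replicates therefore see a
  smoother world than the real one. On the default 40×40 study world the
  population-average bootstrap RMSE is roughly half the Monte-Carlo truth;
  in a noise-free, long-range world it reaches ~65%, and with an
  amplitude-preserving local interpolator (`idw_k=2`) it comes within a few
  percent. This is the classical regime condition of pseudo-population
  bootstraps — calibration requires the attribute surface to be smooth at
  the sampling scale — and is asserted as a monotone property in the test
  suite. Error maps on noise-dominated populations should be read as lower
  bounds.
* Geographic (lon/lat) coordinates are accepted but distances are computed
  on the coordinates as given; use a projected CRS for metric IDW.
* Block contiguity is taken on trust (only counts and membership are
  validated); contiguity checking would require topology the plain-table
  input does not carry.
* No kriging, no analytic HT variance, no unequal-probability designs.

## I/O formats

Populations travel as CSV attribute tables (pixel_id, x, y, block, value,
eligible, plus predictor columns; NA dialects normalized on read) with a
JSON grid sidecar; output rasters are single-band ESRI ASCII grids
(nodata −9999) readable by any GDAL-based tool; scene stacks are
directories of multi-band float32 TIFFs plus a JSON manifest (date, scene
cloud fraction, band order). Numeric columns round-trip losslessly
(`%.17g` on write, round-trip float parsing on read).

## Problem sizes in the tests

The suite exercises 40×40-pixel worlds with 40 blocks (the case study's
~1:40 sampling fraction), bootstrap sizes B ≤ 400 inside tests and B = 300
in the calibration comparison against a Monte-Carlo truth of R = 300
replicates; exhaustive enumeration checks use N ≤ 12 populations where
every sample can be listed. These sizes keep the full suite under a minute
while leaving every asymptotic claim to the documented invariants.
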