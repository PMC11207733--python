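# designmap

Design-based, model-assisted per-pixel mapping of a continuous attribute —
forest volume density is the motivating case — over a finite population of
grid pixels, with a per-pixel root-mean-square-error map obtained by
pseudo-population bootstrap.

## Who this is for

Forest inventory and remote-sensing practitioners who hold (a) a gridded
area of interest carved into blocks, (b) a probabilistic field sample of
pixels (simple random sampling without replacement, one-per-stratum
stratified sampling, or systematic sampling), and (c) wall-to-wall spectral
predictors (e.g. yearly medoid composites of Sentinel-2 bands), and who want
a wall-to-wall map whose total is design-consistent *and* a map of how wrong
each pixel may be — not a single map-wide accuracy figure.

## The estimator

Let U be the eligible pixel population, s ⊂ U the field sample with
inclusion probabilities π_i, and y_i the attribute (m³/m²) measured at
sampled pixels. The map is built in four steps plus an error step:

1. **Variable selection.** Candidate predictors are pre-filtered for
   collinearity (|r| > 0.95 against a better-ranked candidate drops it),
   then entered by greedy forward search under the Gaussian AIC
   `n·log(RSS/n) + 2k`, capped at ⌊n/10⌋ predictors.
2. **Regression.** OLS of y on the selected predictors; predictions ŷ_j
   for every pixel j ∈ U.
3. **Residual interpolation.** Sample residuals ê_i = y_i − ŷ_i are spread
   to all pixels by inverse distance weighting, w_i ∝ d_i^(−2) (a sampled
   pixel receives its own residual back exactly), giving the raw map
   m_j = ŷ_j + IDW(ê)_j.
4. **Harmonization.** With the Horvitz–Thompson total
   T̂ = Σ_s y_i / π_i, every pixel is scaled by the single factor
   T̂ / Σ_j m_j, so the map total *equals* the design-unbiased estimate.
5. **Error map.** The final map is treated as a pseudo-population: B ≥ 1000
   bootstrap samples are drawn under the *same* design and size, steps 1–4
   are re-run on each (variable selection included), and
   RMSE_j = √(B⁻¹ Σ_b (m_j^(b) − m_j)²).

The model only assists interpolation; all uncertainty statements come from
the sampling design.

A compositing stage is included for building the predictors locally: scene
filtering by date window and scene-level cloud cover, per-cell cloud masking
from cloud-probability layers, per-year **medoid** composites (the
observation closest in summed squared per-band difference to the per-band
median), and aggregation of composite cells onto analysis pixels (mean of
covered cells, or bilinear at the centroid).

## Worked example

```python
import numpy as np
import designmap as dm

# a 40x40 synthetic world: 40 one-row blocks, 6 spectral predictors,
# spatially structured truth around 0.04 m3/m2 (~400 m3/ha)
pop, truth = dm.simulate_population(nx=40, ny=40, n_blocks=40, seed=7)
design = dm.design_from_population(pop, "OPSS")
pop_s = dm.sample_and_observe(pop, truth, design, np.random.default_rng(11))

res = dm.PixelMapModel(pop_s).fit()      # scheme auto-detected from blocks
print(res.summary())
err = res.bootstrap_rmse(B=300, seed=13)
print(err.summary())
```

prints

```
Design-based pixel map
======================================================
Sampling scheme:            OPSS
Sampled / eligible pixels:  40 / 1600
HT total:                   62.5496
Raw map total:              60.844
Harmonization factor:       1.028033
Mean pixel estimate:        0.0390935
------------------------------------------------------
coef                  estimate
intercept            0.0374327
p3                   0.0110769
p1                   0.0108176
p2                 -0.00769202
======================================================
{'B': 300, 'mean_rmse': 0.0031411600445007863, 'min_rmse': 0.001097920830617147,
 'max_rmse': 0.01852133648934709, 'n_failures': 0, 'seed': 13}
```

Reading this: the Horvitz–Thompson estimate of the total volume is
62.55 m³/m²·pixel; the raw regression+IDW map summed to 60.84, so every
pixel was scaled up by 1.028 to conserve the design-based total. The mean
pixel estimate of 0.0391 m³/m² is 390.9 m³/ha; the mean per-pixel bootstrap
RMSE of 0.0031 m³/m² is 31.4 m³/ha, with the worst pixels near 185 m³/ha.

The same pipeline runs from a shell:

```sh
designmap simulate population --out world --seed 7
designmap sample --input world/population.csv --scheme opss \
    --truth world/truth.csv --seed 11 --out world/sampled.csv
designmap run --input world/sampled.csv --B 1000 --seed 13 --out-dir world/run
```

which writes the estimate/RMSE tables (CSV), ESRI ASCII grid rasters, and a
JSON run report. `designmap simulate scenes` + `designmap compose` build
predictor columns from a (synthetic or on-disk) scene stack first.

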