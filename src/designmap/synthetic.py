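"""Synthetic populations, scene stacks, and Monte-Carlo oracles.

The generator emulates the structure the estimator assumes: a gridded area
of interest carved into contiguous blocks, partial eligibility (non-forest
pixels), predictors that are smooth random fields, and a truth surface that
is a linear combination of the predictors plus a spatially autocorrelated
residual field plus independent noise, clamped at zero (densities are
non-negative).  The full truth is returned alongside the population so
Monte-Carlo oracles can score any estimator against it.

Default magnitudes mimic a volume-density survey: truth averages a few
hundredths of m³/m² (hundreds of m³/ha), with spatial and white noise a
fraction of that.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .population import GridDefinition, PixelPopulation, tessellate_grid
from .compositing import Scene, SceneStack, DEFAULT_BANDS
from .model import build_map

__all__ = ["SyntheticTruth", "simulate_population", "simulate_scene_stack",
           "sample_and_observe", "monte_carlo_rmse_oracle"]


@dataclass
class SyntheticTruth:
    """Full response surface and the parameters that generated it."""

    values: np.ndarray  # aligned with the population table
    beta_true: np.ndarray  # intercept first
    spatial_range: float  # Gaussian-kernel sigma, in pixels
    sd_spatial: float
    sd_noise: float
    seed: int | None = None

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame({"truth": self.values}).to_csv(path, index=False,
                                                    float_format="%.17g")
        return path

    @classmethod
    def from_csv(cls, path: str | Path, **params) -> "SyntheticTruth":
        vals = pd.read_csv(path,
                           float_precision="round_trip")["truth"].to_numpy(float)
        return cls(values=vals, beta_true=params.get("beta_true", np.array([])),
                   spatial_range=params.get("spatial_range", np.nan),
                   sd_spatial=params.get("sd_spatial", np.nan),
                   sd_noise=params.get("sd_noise", np.nan))


def _smooth_field(shape: tuple[int, int], sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian-kernel-smoothed white noise (sigma in pixels)."""
    z = rng.standard_normal(shape)
    if sigma > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma, mode="reflect")
    z = z - z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def simulate_population(nx: int = 40, ny: int = 40, n_blocks: int = 40,
                        p_predictors: int = 6,
                        beta: np.ndarray | None = None,
                        spatial_range: float = 5.0,
                        sd_spatial: float = 0.008,
                        sd_noise: float = 0.004,
                        eligibility_fraction: float = 1.0,
                        pixel_side: float = 23.0,
                        seed: int | None = None,
                        ) -> tuple[PixelPopulation, SyntheticTruth]:
    """Generate a gridded population with known truth.

    ``beta`` is (intercept, coef_1..coef_p) in attribute units; the default
    gives a mean truth around 0.04 m³/m² (≈400 m³/ha) with predictor signal
    comparable to the residual structure.  Responses are all missing — draw
    a sample and reveal them with :func:`sample_and_observe`.
    """
    if nx <= 0 or ny <= 0:
        raise ValidationError("grid dimensions must be positive")
    if nx * ny < n_blocks:
        raise ValidationError("more blocks than pixels")
    rng = np.random.default_rng(seed)
    pop = tessellate_grid((0.0, 0.0, nx * pixel_side, ny * pixel_side),
                          pixel_side, n_blocks)
    n = pop.n_pixels

    if beta is None:
        signs = np.resize([1.0, -0.7, 0.5, -0.4, 0.3, -0.2], p_predictors)
        beta = np.concatenate([[0.04], 0.01 * signs])
    beta = np.asarray(beta, float)
    if len(beta) != p_predictors + 1:
        raise ValidationError("beta must have p_predictors + 1 entries")

    df = pop.data.copy()
    X = np.empty((n, p_predictors))
    for j in range(p_predictors):
        smooth = _smooth_field((ny, nx), spatial_range, rng).ravel()[:n]
        white = rng.standard_normal(n)
        X[:, j] = 0.8 * smooth + 0.2 * white
        df[f"p{j + 1}"] = X[:, j]

    spatial = _smooth_field((ny, nx), spatial_range, rng).ravel()[:n] * sd_spatial
    noise = rng.standard_normal(n) * sd_noise
    truth = beta[0] + X @ beta[1:] + spatial + noise
    truth = np.maximum(truth, 0.0)

    if eligibility_fraction < 1.0:
        n_out = int(round((1.0 - eligibility_fraction) * n))
        out_idx = rng.choice(n, size=n_out, replace=False)
        elig = np.ones(n, bool)
        elig[out_idx] = False
        df["eligible"] = elig

    pop = PixelPopulation(df, pixel_side=pixel_side, grid=pop.grid)
    return pop, SyntheticTruth(values=truth, beta_true=beta,
                               spatial_range=spatial_range,
                               sd_spatial=sd_spatial, sd_noise=sd_noise,
                               seed=seed)


def sample_and_observe(pop: PixelPopulation, truth: SyntheticTruth,
                       design, rng=None) -> PixelPopulation:
    """Draw a sample under the design and reveal the truth there."""
    from .design import draw_sample

    sample = draw_sample(pop, design, rng)
    ids = pop.data["pixel_id"].to_numpy()
    truth_by_id = dict(zip(ids, truth.values))
    return pop.with_responses(sample.pixel_ids,
                              [truth_by_id[i] for i in sample.pixel_ids])


def simulate_scene_stack(grid: GridDefinition | tuple[int, int],
                         n_scenes: int = 6,
                         n_bands: int = 10,
                         cloud_cover_fraction: float = 0.2,
                         seed: int | None = None,
                         year: int = 2020,
                         window: tuple[str, str] = ("06-10", "08-20"),
                         scene_noise_sd: float = 0.01,
                         ) -> SceneStack:
    """Scenes = shared latent band surfaces + per-scene noise + cloud blobs.

    Cloud blobs are smooth random fields thresholded at the requested cover
    fraction; cloud probability is ~100 inside a blob and near zero outside.
    Acquisition dates are spread evenly over ``window`` within ``year``.
    """
    if n_scenes < 1:
        raise ValidationError("n_scenes must be >= 1")
    if isinstance(grid, tuple):
        ny, nx = grid
        grid = GridDefinition(x0=0.0, y0=ny * 10.0, nx=nx, ny=ny,
                              pixel_side=10.0)
    rng = np.random.default_rng(seed)
    ny, nx = grid.ny, grid.nx
    band_names = tuple(DEFAULT_BANDS[:n_bands]) if n_bands <= len(DEFAULT_BANDS) \
        else tuple(DEFAULT_BANDS) + tuple(f"b{i}" for i in range(len(DEFAULT_BANDS), n_bands))

    latent = np.stack([0.2 + 0.1 * _smooth_field((ny, nx), 4.0, rng)
                       for _ in range(n_bands)])
    latent = np.clip(latent, 0.0, None)

    import datetime as _dt
    d0 = _dt.date.fromisoformat(f"{year}-{window[0]}")
    d1 = _dt.date.fromisoformat(f"{year}-{window[1]}")
    span = max((d1 - d0).days, 0)

    scenes = []
    for i in range(n_scenes):
        bands = np.clip(latent + scene_noise_sd * rng.standard_normal(latent.shape),
                        0.0, None)
        blob = _smooth_field((ny, nx), 6.0, rng)
        if cloud_cover_fraction <= 0:
            prob = np.zeros((ny, nx))
        else:
            cut = np.quantile(blob, 1.0 - cloud_cover_fraction)
            prob = np.where(blob >= cut,
                            95.0 + 5.0 * rng.random((ny, nx)),
                            5.0 * rng.random((ny, nx)))
        frac = float((prob >= 50).mean() * 100)
        offset = 0 if n_scenes == 1 else round(i * span / (n_scenes - 1))
        date = (d0 + _dt.timedelta(days=offset)).isoformat()
        scenes.append(Scene(date=date, bands=bands, band_names=band_names,
                            cloud_prob=prob, cloud_fraction=frac))
    return SceneStack(scenes=tuple(scenes), grid=grid)


def monte_carlo_rmse_oracle(pop: PixelPopulation, truth: SyntheticTruth,
                            design, R: int = 300, seed: int | None = None,
                            map_kwargs: dict | None = None) -> np.ndarray:
    """True per-pixel RMSE of the mapping pipeline under the design.

    Repeats R times: draw a real sample from the truth, build the map, and
    record the squared error against the truth at every eligible pixel;
    returns the per-pixel root mean.  This is the independent yardstick the
    bootstrap error map is calibrated against.
    """
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    acc = np.zeros(pop.n_pixels)
    for r, child in enumerate(ss.spawn(R)):
        rng = np.random.default_rng(child)
        pop_r = sample_and_observe(pop, truth, design, rng)
        amap = build_map(pop_r, design, **(map_kwargs or {}))
        err = amap.estimates - truth.values
        acc += np.where(np.isnan(err), 0.0, err ** 2)
    rmse = np.sqrt(acc / R)
    rmse[~pop.eligible_mask] = np.nan
    return rmse
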