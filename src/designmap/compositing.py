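"""Scene filtering, cloud masking, medoid compositing, and predictor tables.

The predictor stage turns a multi-date stack of spectral scenes into one
cloud-free composite per year and aggregates its bands onto the analysis
pixels.  The compositor is a medoid: for every cell, among the valid
(cloud-free) observations, it keeps the full band vector of the acquisition
closest — in summed squared per-band difference — to the per-band median at
that cell.  Copying an actual observation (rather than the median itself)
keeps band ratios radiometrically consistent.

Scene stacks live in memory as numpy grids; on disk they are a directory of
multi-band TIFFs plus a JSON manifest (see :func:`read_scene_stack`).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .population import GridDefinition, PixelPopulation

__all__ = ["Scene", "SceneStack", "Composite", "filter_scenes",
           "mask_clouds", "medoid_composite", "aggregate_to_pixels",
           "build_predictor_table", "read_scene_stack", "write_scene_stack",
           "DEFAULT_BANDS"]

#: the ten spectral bands the predictor stage works with by default
DEFAULT_BANDS = ("red", "green", "blue", "nir", "redE1", "redE2", "redE3",
                 "redE4", "swir1", "swir2")


@dataclass(frozen=True)
class Scene:
    """One acquisition: reflectance bands + cloud probability on one grid."""

    date: str  # ISO YYYY-MM-DD
    bands: np.ndarray  # (n_bands, ny, nx), non-negative reflectance
    band_names: tuple[str, ...]
    cloud_prob: np.ndarray  # (ny, nx) in [0, 100]
    cloud_fraction: float  # scene-level cloud cover, %
    valid: np.ndarray | None = None  # (ny, nx) bool; None = all valid

    def __post_init__(self):
        if self.bands.ndim != 3 or self.bands.shape[0] != len(self.band_names):
            raise ValidationError("bands must be (n_bands, ny, nx)")
        if self.cloud_prob.shape != self.bands.shape[1:]:
            raise ValidationError("cloud_prob shape mismatch")
        if np.nanmin(self.cloud_prob) < 0 or np.nanmax(self.cloud_prob) > 100:
            raise ValidationError("cloud probability outside [0, 100]")
        if np.nanmin(self.bands) < 0:
            raise ValidationError("negative reflectance")
        _dt.date.fromisoformat(self.date)

    @property
    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.bands.shape[1:], bool)
        return self.valid


@dataclass(frozen=True)
class SceneStack:
    """Date-ordered scenes sharing one grid."""

    scenes: tuple[Scene, ...]
    grid: GridDefinition

    def __post_init__(self):
        shapes = {s.bands.shape for s in self.scenes}
        if len(shapes) > 1:
            raise ValidationError(f"scenes differ in shape: {shapes}")
        names = {s.band_names for s in self.scenes}
        if len(names) > 1:
            raise ValidationError("scenes differ in band names")
        object.__setattr__(self, "scenes",
                           tuple(sorted(self.scenes, key=lambda s: s.date)))

    @property
    def n_scenes(self) -> int:
        return len(self.scenes)

    @property
    def band_names(self) -> tuple[str, ...]:
        return self.scenes[0].band_names


@dataclass(frozen=True)
class Composite:
    """Per-band medoid grids for one compositing period."""

    bands: np.ndarray  # (n_bands, ny, nx); NaN where invalid
    band_names: tuple[str, ...]
    valid: np.ndarray  # (ny, nx) bool: >= 1 valid observation existed
    grid: GridDefinition
    source_index: np.ndarray | None = None  # chosen scene per cell


def filter_scenes(stack: SceneStack, start_date: str, end_date: str,
                  max_cloud_pct: float) -> SceneStack:
    """Keep scenes dated within [start_date, end_date] with cloud cover
    below ``max_cloud_pct`` percent."""
    d0, d1 = _dt.date.fromisoformat(start_date), _dt.date.fromisoformat(end_date)
    if d1 < d0:
        raise ValidationError("end_date before start_date")
    kept = tuple(s for s in stack.scenes
                 if d0 <= _dt.date.fromisoformat(s.date) <= d1
                 and s.cloud_fraction < max_cloud_pct)
    if not kept:
        raise ValidationError(
            f"no scenes in window {start_date}..{end_date} below "
            f"{max_cloud_pct}% cloud")
    return replace(stack, scenes=kept)


def mask_clouds(stack: SceneStack, prob_threshold: float = 50.0) -> SceneStack:
    """Invalidate every cell whose cloud probability >= threshold."""
    masked = tuple(
        replace(s, valid=s.valid_mask & (s.cloud_prob < prob_threshold))
        for s in stack.scenes)
    return replace(stack, scenes=masked)


def medoid_composite(stack: SceneStack) -> Composite:
    """Per cell, keep the band vector closest to the per-band median.

    Distance is the sum over bands of squared differences to the per-band
    median of the valid observations; ties go to the earliest acquisition.
    Cells with no valid observation are NaN and flagged in ``valid``.
    """
    if stack.n_scenes == 0:
        raise ValidationError("empty scene stack")
    arr = np.stack([s.bands for s in stack.scenes])          # (S, B, H, W)
    vmask = np.stack([s.valid_mask for s in stack.scenes])   # (S, H, W)
    vals = np.where(vmask[:, None], arr, np.nan)
    with np.errstate(invalid="ignore"), _suppress_allnan():
        med = np.nanmedian(vals, axis=0)                     # (B, H, W)
    d = np.sum((arr - med) ** 2, axis=1)                     # (S, H, W)
    d = np.where(vmask, d, np.inf)
    choice = np.argmin(d, axis=0)                            # first = earliest
    out = np.take_along_axis(arr, choice[None, None], axis=0)[0]
    any_valid = vmask.any(axis=0)
    out = np.where(any_valid[None], out, np.nan)
    return Composite(bands=out, band_names=stack.band_names,
                     valid=any_valid, grid=stack.grid,
                     source_index=np.where(any_valid, choice, -1))


class _suppress_allnan:
    """Silence numpy's all-NaN-slice warning (expected at fully cloudy cells)."""

    def __enter__(self):
        import warnings
        self._cm = warnings.catch_warnings()
        self._cm.__enter__()
        import warnings as w
        w.filterwarnings("ignore", message="All-NaN slice")
        return self

    def __exit__(self, *exc):
        return self._cm.__exit__(*exc)


# ---------------------------------------------------------------------------
# aggregation onto analysis pixels
# ---------------------------------------------------------------------------

def _pixel_index_lookup(pop: PixelPopulation) -> tuple[GridDefinition, np.ndarray]:
    """Map (row, col) of the analysis grid to row numbers of pop.data."""
    grid = pop.grid
    if grid is None or grid.nx == 0:
        raise ValidationError("population lacks a grid definition")
    lut = np.full(grid.ny * grid.nx, -1, dtype=np.int64)
    col = np.floor((pop.data["x"].to_numpy() - grid.x0) / grid.pixel_side).astype(int)
    row = np.floor((grid.y0 - pop.data["y"].to_numpy()) / grid.pixel_side).astype(int)
    inside = (col >= 0) & (col < grid.nx) & (row >= 0) & (row < grid.ny)
    if not inside.all():
        raise ValidationError("population centroids outside their own grid")
    lut[row * grid.nx + col] = np.arange(len(pop.data))
    return grid, lut


def aggregate_to_pixels(comp: Composite, pop: PixelPopulation,
                        method: str = "mean") -> pd.DataFrame:
    """Per-band predictor values at each analysis pixel.

    ``mean`` averages the composite cells whose centers fall inside the
    analysis pixel (invalid cells excluded); ``bilinear`` resamples each
    band at the analysis-pixel centroid from its four neighboring cell
    centers.  Pixels with no valid contribution get NaN (caught later by
    population validation unless gap-filled).
    """
    if method not in ("mean", "bilinear"):
        raise ValidationError(f"unknown aggregation method '{method}'")
    pgrid, lut = _pixel_index_lookup(pop)
    cg = comp.grid
    nb = len(comp.band_names)
    n = pop.n_pixels
    out = np.full((nb, n), np.nan)

    if method == "mean":
        rr, cc = np.meshgrid(np.arange(cg.ny), np.arange(cg.nx), indexing="ij")
        cx = cg.x0 + (cc + 0.5) * cg.pixel_side
        cy = cg.y0 - (rr + 0.5) * cg.pixel_side
        pcol = np.floor((cx - pgrid.x0) / pgrid.pixel_side).astype(int)
        prow = np.floor((pgrid.y0 - cy) / pgrid.pixel_side).astype(int)
        inside = ((pcol >= 0) & (pcol < pgrid.nx) &
                  (prow >= 0) & (prow < pgrid.ny) & comp.valid)
        tgt = lut[prow[inside] * pgrid.nx + pcol[inside]]
        keep = tgt >= 0
        tgt = tgt[keep]
        counts = np.zeros(n)
        np.add.at(counts, tgt, 1.0)
        for b in range(nb):
            vals = comp.bands[b][inside][keep]
            acc = np.zeros(n)
            np.add.at(acc, tgt, vals)
            with np.errstate(invalid="ignore"):
                out[b] = np.where(counts > 0, acc / counts, np.nan)
    else:  # bilinear at the analysis-pixel centroid
        px = pop.data["x"].to_numpy(float)
        py = pop.data["y"].to_numpy(float)
        # fractional cell coordinates of the target point (cell centers at .5)
        fx = (px - cg.x0) / cg.pixel_side - 0.5
        fy = (cg.y0 - py) / cg.pixel_side - 0.5
        c0 = np.clip(np.floor(fx).astype(int), 0, cg.nx - 1)
        r0 = np.clip(np.floor(fy).astype(int), 0, cg.ny - 1)
        c1 = np.clip(c0 + 1, 0, cg.nx - 1)
        r1 = np.clip(r0 + 1, 0, cg.ny - 1)
        wx = np.clip(fx - c0, 0.0, 1.0)
        wy = np.clip(fy - r0, 0.0, 1.0)
        band_nan = np.where(comp.valid[None], comp.bands, np.nan)
        for b in range(nb):
            g = band_nan[b]
            out[b] = ((1 - wy) * ((1 - wx) * g[r0, c0] + wx * g[r0, c1]) +
                      wy * ((1 - wx) * g[r1, c0] + wx * g[r1, c1]))
    return pd.DataFrame({name: out[i] for i, name in enumerate(comp.band_names)},
                        index=pop.data.index)


def build_predictor_table(stacks: dict[int, SceneStack],
                          pop: PixelPopulation,
                          start_date: str | None = None,
                          end_date: str | None = None,
                          max_cloud_pct: float = 20.0,
                          cloud_prob_threshold: float = 50.0,
                          method: str = "mean",
                          gap_fill: bool = False) -> PixelPopulation:
    """One medoid composite per year -> predictor columns ``<band>_<year>``.

    ``stacks`` maps year -> SceneStack; ``start_date``/``end_date`` are
    month-day strings (e.g. "06-10") applied within each year, or None to
    skip date filtering.  Returns a new population carrying
    ``n_bands * n_years`` predictor columns; centroid coordinates stay in
    the table for the interpolator but are not predictors.

    A pixel left with no valid contributing cells (persistent cloud) keeps a
    missing predictor, which population validation rejects; ``gap_fill``
    instead imputes the across-pixel mean of the covered pixels.
    """
    years = list(stacks)
    if len(set(years)) != len(years):
        raise ValidationError("duplicate composite year")
    if not years:
        raise ValidationError("at least one compositing year required")
    df = pop.data.copy()
    for year in years:
        stack = stacks[year]
        if start_date and end_date:
            stack = filter_scenes(stack, f"{year}-{start_date}",
                                  f"{year}-{end_date}", max_cloud_pct)
        stack = mask_clouds(stack, cloud_prob_threshold)
        comp = medoid_composite(stack)
        cols = aggregate_to_pixels(comp, pop, method=method)
        for band in comp.band_names:
            col = cols[band]
            if gap_fill:
                col = col.fillna(col.mean())
            df[f"{band}_{year}"] = col
    return PixelPopulation(df, pixel_side=pop.pixel_side, grid=pop.grid)


# ---------------------------------------------------------------------------
# on-disk scene stacks: TIFF bands + JSON manifest
# ---------------------------------------------------------------------------

def write_scene_stack(stack: SceneStack, directory: str | Path) -> Path:
    """Write each scene as <date>_bands.tif + <date>_cloud.tif + manifest.json."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"grid": stack.grid.to_dict(),
                "band_names": list(stack.band_names), "scenes": []}
    for i, s in enumerate(stack.scenes):
        stem = f"{s.date}_{i:03d}"
        tifffile.imwrite(directory / f"{stem}_bands.tif",
                         s.bands.astype(np.float32),
                         photometric="minisblack")
        tifffile.imwrite(directory / f"{stem}_cloud.tif",
                         s.cloud_prob.astype(np.float32),
                         photometric="minisblack")
        manifest["scenes"].append({"date": s.date,
                                   "cloud_fraction": float(s.cloud_fraction),
                                   "bands": f"{stem}_bands.tif",
                                   "cloud": f"{stem}_cloud.tif"})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def read_scene_stack(directory: str | Path) -> SceneStack:
    """Read a scene directory written by :func:`write_scene_stack`."""
    import tifffile

    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    grid = GridDefinition.from_dict(manifest["grid"])
    band_names = tuple(manifest["band_names"])
    scenes = []
    for rec in manifest["scenes"]:
        bands = np.asarray(tifffile.imread(directory / rec["bands"]), float)
        cloud = np.asarray(tifffile.imread(directory / rec["cloud"]), float)
        scenes.append(Scene(date=rec["date"], bands=bands,
                            band_names=band_names, cloud_prob=cloud,
                            cloud_fraction=float(rec["cloud_fraction"])))
    return SceneStack(scenes=tuple(scenes), grid=grid)
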