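"""Pixel populations, grid tessellation, and sampling-scheme detection.

A *pixel population* is the finite population the survey targets: every
analysis pixel of the area of interest, with its block (stratum) membership,
eligibility flag (non-forest pixels stay in the file but are excluded from
estimation), field-measured response at the sampled pixels only, and
spectral predictor columns.

Supported formats are deliberately plain-text: a CSV attribute table with a
JSON grid sidecar for input, and CSV + ESRI ASCII grid (.asc) rasters for
output.  The ASCII grid is the standard GDAL-readable text raster; nodata is
written as -9999.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: column names with fixed meaning; everything else is a predictor
RESERVED_COLUMNS = ("pixel_id", "x", "y", "block", "value", "eligible")

#: missing-response dialects normalized to NaN on read
DEFAULT_NA_VALUES = ("", "NA", "N/A", "NaN", "nan", "null", "NULL", "None")

NODATA = -9999.0

SCHEMES = ("SRSWoR", "OPSS", "SYS")


@dataclass(frozen=True)
class GridDefinition:
    """Row-major regular grid: origin is the top-left corner.

    Pixel (row r, col c) has its centroid at
    ``(x0 + (c + 0.5) * pixel_side, y0 - (r + 0.5) * pixel_side)``.
    """

    x0: float
    y0: float
    nx: int
    ny: int
    pixel_side: float
    crs: str | None = None

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    def centroids(self, n_pixels: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Centroid coordinates of the first ``n_pixels`` pixels, row-major."""
        n = self.n_pixels if n_pixels is None else n_pixels
        idx = np.arange(n)
        rows, cols = idx // self.nx, idx % self.nx
        x = self.x0 + (cols + 0.5) * self.pixel_side
        y = self.y0 - (rows + 0.5) * self.pixel_side
        return x, y

    def to_dict(self) -> dict:
        d = {"x0": self.x0, "y0": self.y0, "nx": self.nx, "ny": self.ny,
             "pixel_side": self.pixel_side}
        if self.crs:
            d["crs"] = self.crs
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GridDefinition":
        return cls(x0=float(d["x0"]), y0=float(d["y0"]), nx=int(d["nx"]),
                   ny=int(d["ny"]), pixel_side=float(d["pixel_side"]),
                   crs=d.get("crs"))


@dataclass
class PixelPopulation:
    """The finite population of analysis pixels.

    Attributes
    ----------
    data : DataFrame with columns ``pixel_id, x, y, block, value, eligible``
        plus one numeric column per predictor.  ``value`` is the attribute of
        interest (e.g. volume density, m³/m²); it is NaN at non-sampled
        pixels.
    pixel_side : pixel edge length in meters.
    grid : optional grid definition (required for raster output and for
        aggregating composites onto the population).
    """

    data: pd.DataFrame
    pixel_side: float
    grid: GridDefinition | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- views -------------------------------------------------------------
    @property
    def predictor_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_COLUMNS]

    @property
    def n_pixels(self) -> int:
        return len(self.data)

    @property
    def eligible_mask(self) -> np.ndarray:
        return self.data["eligible"].to_numpy(bool)

    @property
    def sampled_mask(self) -> np.ndarray:
        return self.data["value"].notna().to_numpy()

    @property
    def n_sampled(self) -> int:
        return int(self.sampled_mask.sum())

    @property
    def eligible(self) -> pd.DataFrame:
        return self.data.loc[self.eligible_mask]

    @property
    def sampled(self) -> pd.DataFrame:
        return self.data.loc[self.sampled_mask]

    def coords(self, mask: np.ndarray | None = None) -> np.ndarray:
        xy = self.data[["x", "y"]].to_numpy(float)
        return xy if mask is None else xy[mask]

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        for col in ("pixel_id", "x", "y", "block", "value", "eligible"):
            if col not in df.columns:
                raise ValidationError(f"population table lacks column '{col}'")
        dup = df["pixel_id"][df["pixel_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicated pixel_id values: {sorted(set(dup))[:10]}")
        elig = df["eligible"].to_numpy(bool)
        blk = df["block"]
        bad = df.loc[elig & blk.isna(), "pixel_id"]
        if len(bad):
            raise ValidationError(
                f"eligible pixels with missing block id: {list(bad[:10])}")
        resp = df["value"].notna().to_numpy()
        bad = df.loc[resp & ~elig, "pixel_id"]
        if len(bad):
            raise ValidationError(
                f"response present on ineligible pixels: {list(bad[:10])}")
        bad = df.loc[resp & blk.isna().to_numpy(), "pixel_id"]
        if len(bad):
            raise ValidationError(
                f"response present on pixels with no block: {list(bad[:10])}")
        for p in self.predictor_names:
            n_missing = int(df.loc[elig, p].isna().sum())
            if n_missing:
                raise ValidationError(
                    f"predictor '{p}' has {n_missing} missing values on "
                    "eligible pixels")
        if self.pixel_side <= 0:
            raise ValidationError("pixel_side must be positive")

    def require_sampled(self) -> None:
        if self.n_sampled == 0:
            raise ValidationError("no sampled pixels (all responses missing)")

    def with_responses(self, pixel_ids: Sequence[int],
                       values: Sequence[float]) -> "PixelPopulation":
        """Return a copy whose response is set at ``pixel_ids`` only."""
        df = self.data.copy()
        df["value"] = np.nan
        pos = df.index[df["pixel_id"].isin(pixel_ids)]
        mapper = dict(zip(pixel_ids, values))
        df.loc[pos, "value"] = [mapper[i] for i in df.loc[pos, "pixel_id"]]
        return replace(self, data=df)


@dataclass(frozen=True)
class SamplingDesign:
    """Scheme identity plus block layout and the implied sample size.

    ``block_sizes`` counts *eligible* pixels per block.  For SRSWoR there is
    a single notional block spanning the whole eligible population.  For SYS,
    ``within_block_index`` is the common ordinal position (row-major within
    block) shared by every sampled pixel.
    """

    scheme: str
    block_sizes: pd.Series  # index: block id, values: eligible counts
    sample_size: int
    within_block_index: int | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme '{self.scheme}'")
        if (self.block_sizes <= 0).any():
            empty = list(self.block_sizes.index[self.block_sizes <= 0])
            raise ValidationError(f"blocks with no eligible pixels: {empty[:10]}")
        if self.scheme in ("OPSS", "SYS"):
            if self.sample_size != len(self.block_sizes):
                raise ValidationError(
                    f"{self.scheme} requires one sampled pixel per block: "
                    f"n={self.sample_size} but {len(self.block_sizes)} blocks")
        if self.scheme == "SYS" and self.block_sizes.nunique() != 1:
            raise ValidationError("SYS requires equal eligible block sizes")

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)


# ---------------------------------------------------------------------------
# tessellation
# ---------------------------------------------------------------------------

def partition_blocks(n_pixels: int, n_blocks: int) -> np.ndarray:
    """Sizes of contiguous row-major blocks, as equal as possible.

    If ``n_blocks`` divides ``n_pixels`` all blocks get ``n/m``; otherwise
    the first ``m - 1`` blocks get ``ceil(n/m)`` and the last one holds the
    remainder (e.g. 5449 pixels in 50 blocks -> 49 blocks of 109 and one of
    108).
    """
    if n_blocks <= 0 or n_pixels <= 0:
        raise ValidationError("n_pixels and n_blocks must be positive")
    if n_blocks > n_pixels:
        raise ValidationError("more blocks than pixels")
    if n_pixels % n_blocks == 0:
        return np.full(n_blocks, n_pixels // n_blocks, dtype=int)
    big = math.ceil(n_pixels / n_blocks)
    sizes = np.full(n_blocks, big, dtype=int)
    sizes[-1] = n_pixels - big * (n_blocks - 1)
    if sizes[-1] <= 0:
        # degenerate: ceil blocks over-allocate; shrink the tail greedily
        sizes = np.full(n_blocks, n_pixels // n_blocks, dtype=int)
        sizes[: n_pixels % n_blocks] += 1
    return sizes


def tessellate_grid(extent: tuple[float, float, float, float],
                    pixel_side: float,
                    n_blocks: int,
                    n_pixels: int | None = None,
                    crs: str | None = None) -> PixelPopulation:
    """Tessellate a rectangular extent into square pixels with block runs.

    Parameters
    ----------
    extent : (xmin, ymin, xmax, ymax) in map units.
    pixel_side : pixel edge length (same units).
    n_blocks : number of contiguous blocks to carve.
    n_pixels : optionally keep only the first ``n_pixels`` pixels in
        row-major order — this supports non-rectangular areas of interest
        whose pixel count is not a product of grid dimensions.
    """
    if pixel_side <= 0:
        raise ValidationError("pixel_side must be positive")
    xmin, ymin, xmax, ymax = extent
    nx = int(round((xmax - xmin) / pixel_side))
    ny = int(round((ymax - ymin) / pixel_side))
    if nx <= 0 or ny <= 0:
        raise ValidationError("extent smaller than one pixel")
    grid = GridDefinition(x0=xmin, y0=ymax, nx=nx, ny=ny,
                          pixel_side=pixel_side, crs=crs)
    n = grid.n_pixels if n_pixels is None else int(n_pixels)
    if n > grid.n_pixels:
        raise ValidationError("n_pixels exceeds grid capacity")
    sizes = partition_blocks(n, n_blocks)
    block = np.repeat(np.arange(1, n_blocks + 1), sizes)
    x, y = grid.centroids(n)
    df = pd.DataFrame({
        "pixel_id": np.arange(1, n + 1, dtype=np.int64),
        "x": x, "y": y,
        "block": block,
        "value": np.full(n, np.nan),
        "eligible": np.ones(n, dtype=bool),
    })
    return PixelPopulation(df, pixel_side=pixel_side, grid=grid)


# ---------------------------------------------------------------------------
# scheme detection
# ---------------------------------------------------------------------------

def _within_block_positions(pop: PixelPopulation) -> pd.Series:
    """Ordinal position of each eligible pixel within its block.

    Ordering is deterministic row-major by (y descending, x ascending) of
    centroids, so systematic designs are testable regardless of row order in
    the input file.  Positions start at 0.
    """
    el = pop.eligible
    order = el.sort_values(["y", "x"], ascending=[False, True])
    pos = order.groupby("block").cumcount()
    return pos.reindex(el.index)


def detect_scheme(pop: PixelPopulation,
                  override: str | None = None) -> SamplingDesign:
    """Identify the sampling scheme from the block attribute.

    Every pixel carrying its own unique block id marks SRSWoR (the block is
    then the whole population).  Otherwise exactly one sampled pixel per
    multi-pixel block is required; equal block sizes with a common
    within-block sampled position mark SYS, anything else is OPSS.
    """
    pop.require_sampled()
    el = pop.eligible
    n_sampled = pop.n_sampled
    block_sizes = el.groupby("block").size()
    all_unique = (block_sizes == 1).all() and len(block_sizes) == len(el)

    if all_unique:
        detected = "SRSWoR"
        design = SamplingDesign(
            scheme="SRSWoR",
            block_sizes=pd.Series({0: len(el)}),
            sample_size=n_sampled,
        )
    else:
        sampled_per_block = (
            el.assign(_s=el["value"].notna()).groupby("block")["_s"].sum())
        over = sampled_per_block[sampled_per_block > 1]
        if len(over):
            raise ValidationError(
                "design violated: more than one sampled pixel in block(s) "
                f"{list(over.index[:10])}")
        under = sampled_per_block[sampled_per_block == 0]
        if len(under):
            raise ValidationError(
                "design violated: block(s) with no sampled pixel "
                f"{list(under.index[:10])}")
        pos = _within_block_positions(pop)
        sampled_pos = pos[el["value"].notna()]
        equal_sizes = block_sizes.nunique() == 1
        if equal_sizes and sampled_pos.nunique() == 1:
            detected = "SYS"
            design = SamplingDesign(
                scheme="SYS", block_sizes=block_sizes,
                sample_size=n_sampled,
                within_block_index=int(sampled_pos.iloc[0]))
        else:
            detected = "OPSS"
            design = SamplingDesign(
                scheme="OPSS", block_sizes=block_sizes,
                sample_size=n_sampled)

    if override is not None and override != detected:
        # an override may relax SYS to OPSS (same block structure), nothing else
        if override == "OPSS" and detected == "SYS":
            return SamplingDesign(scheme="OPSS", block_sizes=design.block_sizes,
                                  sample_size=design.sample_size)
        raise ValidationError(
            f"requested scheme '{override}' inconsistent with data "
            f"(detected '{detected}')")
    return design


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".grid.json")


def read_population(path: str | Path,
                    block_col: str = "block",
                    value_col: str = "value",
                    pixel_side: float | None = None,
                    na_values: Iterable[str] = DEFAULT_NA_VALUES,
                    ) -> PixelPopulation:
    """Read a pixel population from a CSV table (+ optional grid sidecar).

    The table must carry ``pixel_id, x, y`` plus the block and value columns
    (names configurable); any other numeric column is a predictor.  Missing
    responses may use any of the usual NA dialects; they are normalized to
    NaN.  A JSON sidecar ``<stem>.grid.json`` supplies the grid definition
    and pixel side; ``pixel_side`` may also be passed directly.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path, na_values=list(na_values), keep_default_na=True,
                     float_precision="round_trip")
    rename = {}
    if block_col != "block":
        rename[block_col] = "block"
    if value_col != "value":
        rename[value_col] = "value"
    df = df.rename(columns=rename)
    if "block" not in df.columns:
        raise ValidationError(
            f"missing block column '{block_col}' in {path.name}")
    if "value" not in df.columns:
        raise ValidationError(
            f"missing value column '{value_col}' in {path.name}")
    if "eligible" not in df.columns:
        df["eligible"] = True
    df["eligible"] = df["eligible"].astype(bool)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")

    grid = None
    side = pixel_side
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        grid = GridDefinition.from_dict(meta)
        side = side or grid.pixel_side
    if side is None:
        raise ValidationError(
            "pixel_side unknown: pass pixel_side= or provide a "
            f"'{sidecar.name}' sidecar")
    pop = PixelPopulation(df, pixel_side=float(side), grid=grid)
    pop.require_sampled()
    return pop


def write_population(pop: PixelPopulation, path: str | Path) -> Path:
    """Write the population table as CSV (+ grid sidecar when known)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pop.data.to_csv(path, index=False, na_rep="NA", float_format="%.17g")
    meta = pop.grid.to_dict() if pop.grid else {"pixel_side": pop.pixel_side}
    if pop.grid is None:
        meta = {"x0": float(pop.data["x"].min() - pop.pixel_side / 2),
                "y0": float(pop.data["y"].max() + pop.pixel_side / 2),
                "nx": 0, "ny": 0, "pixel_side": pop.pixel_side}
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


# -- rasters ----------------------------------------------------------------

def write_ascii_grid(path: str | Path, values: np.ndarray,
                     grid: GridDefinition, nodata: float = NODATA) -> Path:
    """Write a 2-D array as an ESRI ASCII grid (row 0 = northernmost)."""
    path = Path(path)
    arr = np.asarray(values, float)
    if arr.shape != (grid.ny, grid.nx):
        raise ValidationError(
            f"raster shape {arr.shape} != grid ({grid.ny}, {grid.nx})")
    yll = grid.y0 - grid.ny * grid.pixel_side
    header = (f"ncols {grid.nx}\nnrows {grid.ny}\n"
              f"xllcorner {grid.x0!r}\nyllcorner {yll!r}\n"
              f"cellsize {grid.pixel_side!r}\nNODATA_value {nodata!r}\n")
    body = np.where(np.isnan(arr), nodata, arr)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.12g")
    return path


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridDefinition]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)
    nodata = header.get("nodata_value", NODATA)
    arr = np.where(arr == nodata, np.nan, arr)
    nx, ny = int(header["ncols"]), int(header["nrows"])
    side = header["cellsize"]
    grid = GridDefinition(x0=header["xllcorner"],
                          y0=header["yllcorner"] + ny * side,
                          nx=nx, ny=ny, pixel_side=side)
    return arr, grid


def _pixels_to_raster(pop: PixelPopulation, values: np.ndarray) -> np.ndarray:
    grid = pop.grid
    out = np.full((grid.ny, grid.nx), np.nan)
    col = np.floor((pop.data["x"].to_numpy() - grid.x0) / grid.pixel_side)
    row = np.floor((grid.y0 - pop.data["y"].to_numpy()) / grid.pixel_side)
    out[row.astype(int), col.astype(int)] = values
    return out


def write_outputs(pop: PixelPopulation,
                  attr,  # AttributeMap
                  err=None,  # ErrorMap | None
                  prefix: str | Path = "designmap_run",
                  ) -> list[Path]:
    """Write the estimate (and error) products: CSV table + .asc rasters.

    Ineligible pixels are nodata in the rasters and NaN in the table.  When
    no error map is supplied only the estimate products are written, with a
    warning.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = pop.n_pixels
    est = np.asarray(attr.estimates, float)
    if est.shape[0] != n:
        raise ValidationError(
            f"attribute map length {est.shape[0]} != population {n}")
    table = pop.data[["pixel_id", "x", "y", "block", "eligible"]].copy()
    table["estimate"] = np.where(pop.eligible_mask, est, np.nan)
    written: list[Path] = []
    if err is not None:
        rmse = np.asarray(err.rmse, float)
        if rmse.shape[0] != n:
            raise ValidationError(
                f"error map length {rmse.shape[0]} != population {n}")
        table["rmse"] = np.where(pop.eligible_mask, rmse, np.nan)
    else:
        logger.warning("no error map supplied; writing estimate products only")
        warnings.warn("no error map supplied; writing estimate products only",
                      stacklevel=2)
    csv_path = prefix.with_suffix(".csv")
    table.to_csv(csv_path, index=False, na_rep="NA", float_format="%.12g")
    written.append(csv_path)
    if pop.grid is not None and pop.grid.nx > 0:
        est_r = _pixels_to_raster(pop, np.asarray(table["estimate"]))
        written.append(write_ascii_grid(prefix.parent / (prefix.name + "_estimate.asc"),
                                        est_r, pop.grid))
        if err is not None:
            rmse_r = _pixels_to_raster(pop, np.asarray(table["rmse"]))
            written.append(write_ascii_grid(prefix.parent / (prefix.name + "_rmse.asc"),
                                            rmse_r, pop.grid))
    else:
        logger.warning("population has no grid definition; rasters skipped")
    return written
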