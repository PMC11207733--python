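"""Run configuration: documented defaults, YAML round-trip, provenance.

Every knob of the pipeline lives here with its default, so a run report can
echo the exact configuration that produced it.  A YAML file mirrors the CLI
flags; explicit CLI values override the file.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    scheme: sampling-scheme override ("auto" detects from the block column).
    start_date/end_date: compositing window as month-day within each year.
    max_cloud_pct: scene-level cloud-cover cutoff (%), scenes at or above
        are dropped.
    cloud_prob_threshold: per-cell cloud-probability cutoff in [0, 100].
    resample: how composite cells map to analysis pixels (mean | bilinear).
    collinearity_r: |pairwise r| above which a candidate predictor is
        dropped in the selection pre-filter.
    idw_power: inverse-distance-weighting exponent.
    idw_k: IDW neighborhood size (None = all sampled pixels).
    clamp: clamp negative pre-harmonization estimates to zero.
    coords_as_predictors: let centroid coordinates join the candidate pool.
    B: bootstrap replicate count (method floor: 1000).
    seed: root seed; child streams are derived per purpose.
    workers: process count for the bootstrap.
    """

    scheme: str = "auto"
    start_date: str = "06-10"
    end_date: str = "08-20"
    years: tuple[int, ...] = ()
    max_cloud_pct: float = 20.0
    cloud_prob_threshold: float = 50.0
    resample: str = "mean"
    collinearity_r: float = 0.95
    idw_power: float = 2.0
    idw_k: int | None = None
    clamp: bool = True
    coords_as_predictors: bool = False
    max_predictors: int | None = None
    B: int = 1000
    seed: int = 1
    workers: int = 1
    input_path: str | None = None
    output_dir: str = "designmap_out"

    def __post_init__(self):
        if self.scheme not in ("auto", "SRSWoR", "OPSS", "SYS"):
            raise ValidationError(f"unknown scheme '{self.scheme}'")
        if self.resample not in ("mean", "bilinear"):
            raise ValidationError(f"unknown resample method '{self.resample}'")
        if self.B < 1:
            raise ValidationError("B must be >= 1")
        self.years = tuple(int(y) for y in self.years)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["years"] = list(self.years)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path
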