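"""Pseudo-population bootstrap producing the per-pixel RMSE map.

The final harmonized map is treated as a pseudo-population: each bootstrap
replicate draws a fresh sample from it under the *same* design and size as
the original field sample, reads the map values at the drawn pixels as if
they were ground observations, and re-runs the whole mapping pipeline —
variable selection included, so selection uncertainty propagates.  The
per-pixel root mean square error is computed against the final-map value
(the pseudo-population truth):

    rmse_j = sqrt( (1/B) * sum_b (replicate_j^(b) - final_j)^2 )

``center="mean"`` instead centers each pixel on its replicate mean, which
splits the discrepancy into variance and bias terms.

Determinism: replicate ``b`` (attempt ``a`` after failures) always draws
from the seed stream ``SeedSequence([seed, b, a])``, so the error map is
bit-identical for any worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .errors import DesignMapError, NumericalError
from .population import PixelPopulation, SamplingDesign
from .design import draw_sample
from .model import AttributeMap, build_map

logger = logging.getLogger(__name__)

__all__ = ["ErrorMap", "bootstrap_replicate", "bootstrap_error_map"]

_MAX_ATTEMPTS = 10
_MAX_FAILURE_FRACTION = 0.05


@dataclass
class ErrorMap:
    """Per-pixel bootstrap RMSE (attribute units), plus diagnostics."""

    rmse: np.ndarray
    n_replicates: int
    replicate_mean: np.ndarray
    seed: int | None = None
    n_failures: int = 0

    def summary(self) -> dict:
        ok = self.rmse[np.isfinite(self.rmse)]
        return {"B": self.n_replicates,
                "mean_rmse": float(ok.mean()),
                "min_rmse": float(ok.min()),
                "max_rmse": float(ok.max()),
                "n_failures": self.n_failures,
                "seed": self.seed}


def bootstrap_replicate(final_map: AttributeMap, pop: PixelPopulation,
                        design: SamplingDesign,
                        rng: np.random.Generator | int | None = None,
                        map_kwargs: dict | None = None) -> np.ndarray:
    """One replicate: resample the final map and re-run steps 1-4.

    Returns the replicate's per-pixel estimates aligned with the population
    table.
    """
    rng = np.random.default_rng(rng)
    sample = draw_sample(pop, design, rng)
    ids = pop.data["pixel_id"].to_numpy()
    est_by_id = dict(zip(ids, final_map.estimates))
    pseudo_y = [est_by_id[i] for i in sample.pixel_ids]
    pop_b = pop.with_responses(sample.pixel_ids, pseudo_y)
    amap = build_map(pop_b, design, **(map_kwargs or {}))
    return amap.estimates


def _replicate_with_retries(b: int, seed_int: int, final_map: AttributeMap,
                            pop: PixelPopulation, design: SamplingDesign,
                            map_kwargs: dict | None) -> tuple[np.ndarray, int]:
    failures = 0
    for attempt in range(_MAX_ATTEMPTS):
        rng = np.random.default_rng(np.random.SeedSequence([seed_int, b, attempt]))
        try:
            return bootstrap_replicate(final_map, pop, design, rng,
                                       map_kwargs), failures
        except DesignMapError as exc:  # redraw with the next child stream
            failures += 1
            logger.warning("replicate %d attempt %d failed: %s", b, attempt, exc)
    raise NumericalError(
        f"bootstrap replicate {b} failed {_MAX_ATTEMPTS} consecutive times")


def bootstrap_error_map(final_map: AttributeMap, pop: PixelPopulation,
                        design: SamplingDesign, B: int = 1000,
                        seed: int | None = None, workers: int = 1,
                        center: str = "final",
                        map_kwargs: dict | None = None) -> ErrorMap:
    """Run B replicates and assemble the per-pixel RMSE map.

    ``B`` defaults to the method's floor of 1000 replicates.  The result is
    independent of ``workers`` for a fixed seed.
    """
    if B < 1:
        raise NumericalError("B must be >= 1")
    if center not in ("final", "mean"):
        raise NumericalError(f"unknown center '{center}'")
    seed_int = int(seed if seed is not None else 0)

    if workers == 1:
        reps = [_replicate_with_retries(b, seed_int, final_map, pop, design,
                                        map_kwargs) for b in range(B)]
    else:
        reps = Parallel(n_jobs=workers, prefer="processes")(
            delayed(_replicate_with_retries)(b, seed_int, final_map, pop,
                                             design, map_kwargs)
            for b in range(B))
    mats = np.stack([r[0] for r in reps])  # (B, n_pixels)
    n_failures = sum(r[1] for r in reps)
    if n_failures > _MAX_FAILURE_FRACTION * B:
        raise NumericalError(
            f"{n_failures} replicate failures exceed "
            f"{_MAX_FAILURE_FRACTION:.0%} of B={B}")

    rep_mean = mats.mean(axis=0)
    ref = final_map.estimates if center == "final" else rep_mean
    rmse = np.sqrt(np.mean((mats - ref) ** 2, axis=0))
    rmse[~pop.eligible_mask] = np.nan
    return ErrorMap(rmse=rmse, n_replicates=B, replicate_mean=rep_mean,
                    seed=seed, n_failures=n_failures)
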