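"""Sample selection, inclusion probabilities, and the Horvitz-Thompson total.

Three without-replacement designs are supported over the eligible pixels:

* SRSWoR — simple random sampling of n pixels from the whole population,
  first-order inclusion probability π = n/N;
* OPSS — one-per-stratum stratified sampling, one uniform draw per block,
  π = 1/N_h with N_h the eligible count of block h;
* SYS — systematic sampling over equally sized blocks: one within-block
  ordinal position drawn uniformly and replicated in every block, π = 1/K.

Uncertainty in the pipeline comes from the pseudo-population bootstrap, so
joint inclusion probabilities are not needed and are not computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .population import PixelPopulation, SamplingDesign, _within_block_positions

__all__ = ["Sample", "inclusion_probabilities", "draw_sample",
           "horvitz_thompson_total", "design_from_population"]


def design_from_population(pop: PixelPopulation, scheme: str,
                           n: int | None = None) -> SamplingDesign:
    """Build a design from the block structure, before any sample exists.

    For OPSS/SYS the sample size is the block count; for SRSWoR ``n`` must
    be given (the whole eligible population forms one notional block).
    """
    el = pop.eligible
    if len(el) == 0:
        raise ValidationError("no eligible pixels")
    if scheme == "SRSWoR":
        if n is None:
            raise ValidationError("SRSWoR needs an explicit sample size n")
        if not (0 < n <= len(el)):
            raise ValidationError(f"sample size n={n} outside 1..{len(el)}")
        return SamplingDesign(scheme="SRSWoR",
                              block_sizes=pd.Series({0: len(el)}),
                              sample_size=int(n))
    sizes = el.groupby("block").size()
    all_blocks = pop.data.loc[pop.data["block"].notna(), "block"].unique()
    empty = sorted(set(all_blocks) - set(sizes.index))
    if empty:
        raise ValidationError(
            f"block(s) with no eligible pixels: {empty[:10]}")
    return SamplingDesign(scheme=scheme, block_sizes=sizes,
                          sample_size=len(sizes))


@dataclass(frozen=True)
class Sample:
    """A drawn (or observed) sample: unit ids with their design weights."""

    pixel_ids: np.ndarray
    inclusion_probability: np.ndarray  # pi_i in (0, 1]
    scheme: str

    def __post_init__(self):
        if len(self.pixel_ids) != len(self.inclusion_probability):
            raise ValidationError("pixel_ids and probabilities length mismatch")
        if (self.inclusion_probability <= 0).any():
            raise ValidationError("non-positive inclusion probability")

    @property
    def n(self) -> int:
        return len(self.pixel_ids)


def inclusion_probabilities(design: SamplingDesign,
                            pop: PixelPopulation) -> pd.Series:
    """First-order inclusion probability for every eligible pixel.

    Returns a Series indexed by pixel_id.
    """
    el = pop.eligible
    if design.scheme == "SRSWoR":
        n_el = len(el)
        if n_el == 0:
            raise ValidationError("no eligible pixels")
        pi = np.full(n_el, design.sample_size / n_el)
    else:
        sizes = el.groupby("block").size()
        missing = design.block_sizes.index.difference(sizes.index)
        if len(missing):
            raise ValidationError(
                f"block(s) with no eligible pixels: {list(missing[:10])}")
        pi = (1.0 / sizes.loc[el["block"]]).to_numpy()
    return pd.Series(pi, index=el["pixel_id"].to_numpy(), name="pi")


def draw_sample(pop: PixelPopulation, design: SamplingDesign,
                rng: np.random.Generator | int | None = None) -> Sample:
    """Draw one sample under the design; reproducible under a seed."""
    rng = np.random.default_rng(rng)
    el = pop.eligible
    if len(el) == 0:
        raise ValidationError("no eligible pixels")
    pi_all = inclusion_probabilities(design, pop)

    if design.scheme == "SRSWoR":
        ids = rng.choice(el["pixel_id"].to_numpy(), size=design.sample_size,
                         replace=False)
    elif design.scheme == "OPSS":
        ids = (el.groupby("block")["pixel_id"]
               .apply(lambda s: s.iloc[rng.integers(len(s))])
               .to_numpy())
    elif design.scheme == "SYS":
        sizes = el.groupby("block").size()
        if sizes.nunique() != 1:
            raise ValidationError(
                "SYS requires equal eligible counts in every block")
        k = int(sizes.iloc[0])
        position = int(rng.integers(k))
        pos = _within_block_positions(pop)
        ids = el.loc[pos == position, "pixel_id"].to_numpy()
    else:  # pragma: no cover - guarded by SamplingDesign
        raise ValidationError(f"unknown scheme {design.scheme}")

    ids = np.sort(ids)
    return Sample(pixel_ids=ids,
                  inclusion_probability=pi_all.loc[ids].to_numpy(),
                  scheme=design.scheme)


def horvitz_thompson_total(values: np.ndarray, pi: np.ndarray) -> float:
    """The design-unbiased total estimator: sum over the sample of y_i / pi_i."""
    values = np.asarray(values, float)
    pi = np.asarray(pi, float)
    if values.shape != pi.shape:
        raise ValidationError("values and inclusion probabilities differ in length")
    if (pi <= 0).any():
        raise ValidationError("inclusion probabilities must be positive")
    return float(np.sum(values / pi))
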