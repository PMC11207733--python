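"""Unit plumbing for density attributes on square pixels.

The attribute of interest is a density per unit ground area (e.g. wood
volume, m³/m²).  A pixel of side 23 m covers 529 m²; multiplying a density
in m³/m² by 10,000 expresses it in the forester's customary m³/ha
(0.042 m³/m² -> 420 m³/ha).
"""

M2_PER_HA = 10_000.0


def pixel_area_m2(pixel_side_m: float) -> float:
    """Ground area of one square pixel, m²."""
    if pixel_side_m <= 0:
        raise ValueError("pixel side must be positive")
    return pixel_side_m * pixel_side_m


def density_to_m3_per_ha(density_m3_per_m2: float) -> float:
    """Convert a density from m³/m² to m³/ha."""
    return density_m3_per_m2 * M2_PER_HA


def total_from_density(density_m3_per_m2, pixel_side_m: float):
    """Per-pixel total (m³) from a per-pixel density (m³/m²)."""
    return density_m3_per_m2 * pixel_area_m2(pixel_side_m)
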