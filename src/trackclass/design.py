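"""Experimental-design bookkeeping and unit/volume arithmetic.

The microcosm experiment crosses species richness (0-6) with temperature
(15-25 degC in 2 degC steps).  Each richness level has a number of unique
species combinations and replicates per combination; video sampling films a
fixed chamber volume at a fixed frame rate.  The helpers here hold that
arithmetic in one place so that the rest of the pipeline never hard-codes a
volume or a frame count.

All functions keep full float precision internally; rounding for display is
the caller's job (see :func:`round_volume`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field


#: Default richness design: (richness, n unique combinations, n replicates).
DEFAULT_RICHNESS_LEVELS: tuple[tuple[int, int, int], ...] = (
    (0, 1, 5),
    (1, 6, 3),
    (2, 15, 2),
    (3, 10, 2),
    (4, 15, 2),
    (5, 6, 2),
    (6, 1, 5),
)

DEFAULT_TEMPERATURES: tuple[float, ...] = (15.0, 17.0, 19.0, 21.0, 23.0, 25.0)

#: The six study species (ciliates spanning ca. 30-400 um body length).
DEFAULT_SPECIES: tuple[str, ...] = ("Colp", "Dexio", "Loxo", "Para", "Spiro", "Tetra")


@dataclass
class DesignSpec:
    """Static description of the experimental design and video geometry."""

    richness_levels: tuple[tuple[int, int, int], ...] = DEFAULT_RICHNESS_LEVELS
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    total_mix_volume_ml: float = 40.0
    chamber_height_um: float = 600.0
    filmed_area_mm2: float = 68.7
    fps: float = 25.0
    species: tuple[str, ...] = field(default=DEFAULT_SPECIES)

    def __post_init__(self) -> None:
        for richness, combos, reps in self.richness_levels:
            if combos <= 0 or reps <= 0 or richness < 0:
                raise ValueError(
                    f"invalid richness level ({richness}, {combos}, {reps})"
                )
        if self.chamber_height_um <= 0 or self.filmed_area_mm2 <= 0:
            raise ValueError("chamber height and filmed area must be positive")


def enumerate_units(spec: DesignSpec) -> tuple[int, int]:
    """Count experimental units per temperature and in total.

    Returns ``(per_temperature, total)`` where per-temperature is the sum of
    combinations x replicates over richness levels.
    """
    per_temperature = sum(c * r for _, c, r in spec.richness_levels)
    return per_temperature, per_temperature * len(spec.temperatures)


def inoculum_per_species(richness: int, total_mix_volume_ml: float = 40.0) -> float:
    """Volume of each species' stock in the initial mix (mL), full precision."""
    if richness < 1:
        raise ValueError("inoculum undefined for richness 0 (control)")
    return total_mix_volume_ml / richness


def sampled_volume(chamber_height_um: float, filmed_area_mm2: float) -> float:
    """Volume of culture appearing in a video (uL).

    height (mm) x area (mm^2) = mm^3 = uL.
    """
    if chamber_height_um <= 0 or filmed_area_mm2 <= 0:
        raise ValueError("chamber height and filmed area must be positive")
    return chamber_height_um / 1000.0 * filmed_area_mm2


def frames_to_seconds(n_frames: float, fps: float) -> float:
    if fps <= 0:
        raise ValueError("fps must be positive")
    return n_frames / fps


def pixels_to_micron(px: float, scale_um_per_px: float) -> float:
    if scale_um_per_px <= 0:
        raise ValueError("pixel scale must be positive")
    return px * scale_um_per_px


def window_fraction(window_days: float, span_days: float) -> int:
    """Window size as an integer percentage of the sampling span."""
    if window_days <= 0 or span_days <= 0:
        raise ValueError("window and span must be positive")
    if window_days > span_days:
        warnings.warn(
            f"window ({window_days} d) exceeds span ({span_days} d); clipped to 100%",
            stacklevel=2,
        )
        return 100
    return round(100.0 * window_days / span_days)


def count_to_density(
    mean_count_per_frame: float,
    sampled_volume_ul: float,
    dilution: float = 1.0,
) -> float:
    """Convert a mean per-frame individual count to individuals per mL."""
    if sampled_volume_ul <= 0:
        raise ValueError("sampled volume must be positive")
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    return mean_count_per_frame / (sampled_volume_ul / 1000.0) * dilution


def round_volume(volume: float) -> float:
    """One-decimal display rounding for volumes (mL or uL)."""
    return round(volume, 1)
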