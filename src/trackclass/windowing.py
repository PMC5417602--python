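"""Sliding-window training-set assembly and class balancing.

Phenotypes drift with time and temperature, so a classifier trained on the
whole experiment blurs class boundaries.  Training observations are instead
selected from a window around the target sample: within ``window_days`` of
its sampling day (centered, half-width w/2), optionally restricted to the
target temperature, and optionally restricted to the species known to be in
the community (plus the noise class anchored by controls).  At the edges of
the experiment the window is shifted, not shrunk, so training-set size is
preserved.  Class imbalance is then removed by random under-sampling to a
fixed count per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SampleMeta
from .noise import NOISE_LABEL


@dataclass
class WindowConfig:
    window_days: float = 10.0
    temperature_mode: str = "same_only"  # or "all"
    species_pool_mode: str = "composition_only"  # or "all_species"
    include_noise_class: bool = True
    n_per_class: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_days <= 0:
            raise ValueError("window_days must be positive")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.temperature_mode not in ("same_only", "all"):
            raise ValueError(f"unknown temperature_mode {self.temperature_mode!r}")
        if self.species_pool_mode not in ("composition_only", "all_species"):
            raise ValueError(f"unknown species_pool_mode {self.species_pool_mode!r}")


@dataclass
class TrainingSet:
    """Labeled feature vectors with selection provenance."""

    features: pd.DataFrame  # includes a 'species' label column
    provenance: dict = field(default_factory=dict)

    @property
    def class_counts(self) -> dict[str, int]:
        return self.features["species"].value_counts().to_dict()


def window_bounds(
    target_day: float, window_days: float, span: tuple[float, float]
) -> tuple[float, float]:
    """Day range of a centered window, shifted (not shrunk) at the edges."""
    half = window_days / 2.0
    lo, hi = target_day - half, target_day + half
    span_lo, span_hi = span
    width = min(window_days, span_hi - span_lo)
    if lo < span_lo:
        lo, hi = span_lo, span_lo + width
    elif hi > span_hi:
        lo, hi = span_hi - width, span_hi
    return lo, hi


def select_window(
    pool: pd.DataFrame,
    target: SampleMeta,
    config: WindowConfig,
    span: tuple[float, float] | None = None,
) -> TrainingSet:
    """Select labeled training observations around a target community.

    ``pool`` carries one row per labeled trajectory with columns
    ``species`` (class label, :data:`~trackclass.noise.NOISE_LABEL` for
    control trajectories), ``day`` and ``temperature``.  ``span`` is the
    experiment's sampling-day range; by default it is taken from the pool.
    """
    if len(pool) == 0:
        raise ValueError("empty training pool")
    if span is None:
        span = (float(pool["day"].min()), float(pool["day"].max()))
    lo, hi = window_bounds(target.day, config.window_days, span)
    mask = (pool["day"] >= lo) & (pool["day"] <= hi)
    if config.temperature_mode == "same_only":
        mask &= pool["temperature"] == target.temperature
    if config.species_pool_mode == "composition_only":
        allowed = set(target.composition) | {NOISE_LABEL}
        mask &= pool["species"].isin(allowed)
    if not config.include_noise_class:
        mask &= pool["species"] != NOISE_LABEL
    selected = pool.loc[mask].copy()
    if len(selected) == 0:
        raise ValueError(
            f"no training data in window days [{lo}, {hi}] "
            f"(temperature_mode={config.temperature_mode})"
        )
    provenance = {
        "target_sample": target.sample_id,
        "target_day": target.day,
        "target_temperature": target.temperature,
        "window_days": config.window_days,
        "day_range": [lo, hi],
        "temperature_mode": config.temperature_mode,
        "species_pool_mode": config.species_pool_mode,
        "source_samples": sorted(set(map(str, selected["sample_id"]))),
        "source_days": sorted(set(map(float, selected["day"]))),
    }
    return TrainingSet(features=selected, provenance=provenance)


def balance_classes(
    training: TrainingSet,
    n_per_class: int,
    seed: int,
    required_classes: set[str] | None = None,
) -> TrainingSet:
    """Random under-sampling of majority classes to ``n_per_class``.

    Classes with fewer observations keep everything (with a warning);
    sampling is uniform without replacement and deterministic under the
    seed.
    """
    df = training.features
    if required_classes:
        present = set(df["species"].unique())
        absent = sorted(required_classes - present)
        if absent:
            raise ValueError(f"required classes absent from window: {absent}")
    rng = np.random.default_rng(seed)
    parts = []
    for cls in sorted(df["species"].unique()):
        grp = df[df["species"] == cls]
        if len(grp) > n_per_class:
            idx = rng.choice(len(grp), size=n_per_class, replace=False)
            parts.append(grp.iloc[np.sort(idx)])
        else:
            if len(grp) < n_per_class:
                warnings.warn(
                    f"class {cls!r} has only {len(grp)} < {n_per_class} "
                    "observations; keeping all",
                    stacklevel=2,
                )
            parts.append(grp)
    balanced = pd.concat(parts, axis=0)
    provenance = dict(training.provenance)
    provenance["n_per_class"] = n_per_class
    provenance["balance_seed"] = seed
    return TrainingSet(features=balanced, provenance=provenance)
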