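"""Trajectory quality filters and species-specific morphology bounds.

Two stringency levels share the same base criteria (net displacement,
duration, detection rate, median step length) and differ only in the mean
speed floor: 50 um/s for test data (keep every plausible ciliate), 200 um/s
for training data (debris usually moves more slowly, so a fast floor keeps
training labels clean).  Training data are additionally screened against
per-species area bounds that may drift with time.

Criteria use the inequalities implied by their wording: "at least" -> >=,
"greater than" -> >.  Filter reports attribute each removed trajectory to
the first failing criterion, evaluated in a fixed order, so reports are
deterministic and auditable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Criterion evaluation order for first-failure attribution.
CRITERIA = ("net_displacement", "duration", "detection_rate", "median_step", "speed")


@dataclass
class FilterConfig:
    min_net_displacement: float = 50.0  # um, >=
    min_duration: float = 0.2  # s, >
    min_detection_rate: float = 0.8  # fraction, >=
    min_median_step: float = 2.0  # um, >
    min_mean_speed_test: float = 50.0  # um/s, >
    min_mean_speed_train: float = 200.0  # um/s, >

    def __post_init__(self) -> None:
        vals = (
            self.min_net_displacement,
            self.min_duration,
            self.min_detection_rate,
            self.min_median_step,
            self.min_mean_speed_test,
            self.min_mean_speed_train,
        )
        if any(v < 0 for v in vals):
            raise ValueError("filter thresholds must be >= 0")
        if self.min_mean_speed_train < self.min_mean_speed_test:
            raise ValueError("training speed floor must be >= test speed floor")


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    removed_by: dict[str, int] = field(default_factory=dict)
    kill_lists: dict[str, list] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed_by": dict(self.removed_by),
        }


def min_detected_frames(span_frames: int, min_rate: float) -> int:
    """Smallest detection count satisfying a rate over a frame span.

    A trajectory spanning ten frames at rate 0.8 needs at least eight
    detections: ceil(rate * span), with a guard against float fuzz.
    """
    if span_frames < 1:
        raise ValueError("span must be >= 1 frame")
    if not 0 < min_rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    return math.ceil(min_rate * span_frames - 1e-9)


def apply_base_filter(
    features: pd.DataFrame, config: FilterConfig, mode: str
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the base quality filter at test or train stringency."""
    if mode == "test":
        speed_floor = config.min_mean_speed_test
    elif mode == "train":
        speed_floor = config.min_mean_speed_train
    else:
        raise ValueError(f"unknown filter mode {mode!r} (expected 'test' or 'train')")

    checks = {
        "net_displacement": features["net_displacement"]
        >= config.min_net_displacement,
        "duration": features["duration"] > config.min_duration,
        "detection_rate": features["detection_rate"] >= config.min_detection_rate,
        "median_step": features["median_step"] > config.min_median_step,
        "speed": features["gross_speed"] > speed_floor,
    }
    keep = np.ones(len(features), dtype=bool)
    report = FilterReport(n_input=len(features), n_retained=0)
    attributed = np.zeros(len(features), dtype=bool)
    for criterion in CRITERIA:
        ok = checks[criterion].to_numpy()
        newly_failed = ~ok & ~attributed
        attributed |= newly_failed
        report.removed_by[criterion] = int(newly_failed.sum())
        report.kill_lists[criterion] = list(
            features.loc[newly_failed, "trajectory_id"]
        )
        keep &= ok
    retained = features.loc[keep].copy()
    report.n_retained = len(retained)
    return retained, report


@dataclass
class SpeciesBounds:
    """Per-species area bounds (um^2) indexed by sampling day.

    Bounds are given at knot days and linearly interpolated between them;
    outside the knot range the nearest knot applies.  They encode the
    curated per-species size envelope, allowed to shift as morphology
    drifts over the experiment.
    """

    bounds: dict[str, list[tuple[float, float, float]]]  # species -> [(day, lo, hi)]

    def __post_init__(self) -> None:
        for sp, knots in self.bounds.items():
            knots.sort(key=lambda k: k[0])
            for day, lo, hi in knots:
                if lo >= hi:
                    raise ValueError(f"{sp}: min_area {lo} >= max_area {hi} at day {day}")

    @classmethod
    def constant(cls, bounds: dict[str, tuple[float, float]]) -> "SpeciesBounds":
        return cls({sp: [(0.0, lo, hi)] for sp, (lo, hi) in bounds.items()})

    def bounds_at(self, species: str, day: float) -> tuple[float, float]:
        knots = self.bounds[species]
        days = np.array([k[0] for k in knots])
        lo = float(np.interp(day, days, [k[1] for k in knots]))
        hi = float(np.interp(day, days, [k[2] for k in knots]))
        return lo, hi

    def __contains__(self, species: str) -> bool:
        return species in self.bounds


def apply_morphology_bounds(
    features: pd.DataFrame,
    bounds: SpeciesBounds,
    sampling_day: float,
    label_col: str = "species",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain labeled trajectories whose mean area lies in the species band.

    Labels without configured bounds pass through with a warning (the band
    is curator-supplied and may not cover every class, e.g. noise).
    """
    keep = np.ones(len(features), dtype=bool)
    warned: set[str] = set()
    for i, (_, row) in enumerate(features.iterrows()):
        sp = row[label_col]
        if sp not in bounds:
            if sp not in warned:
                warnings.warn(f"no morphology bounds for {sp!r}; passing through",
                              stacklevel=2)
                warned.add(sp)
            continue
        lo, hi = bounds.bounds_at(sp, sampling_day)
        keep[i] = lo <= row["mean_area"] <= hi
    return features.loc[keep].copy(), features.loc[~keep].copy()
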