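"""Trajectory-level morphology and movement features.

Each tracked particle contributes one feature vector summarising its
per-frame morphology (area, perimeter, ellipse axes, aspect ratio) and its
movement (per-step speeds and turning behaviour).  Fifteen features are
computed per trajectory:

==================  =============================================
mean_area, sd_area  mean / SD of particle area (um^2)
mean_perimeter,
sd_perimeter        mean / SD of perimeter length (um)
mean_major,
sd_major            mean / SD of fitted-ellipse major axis (um)
mean_minor,
sd_minor            mean / SD of minor axis (um)
mean_ar, sd_ar      mean / SD of aspect ratio (dimensionless)
sd_turning          circular SD of movement direction (rad)
gross_speed,
sd_gross_speed,
max_gross_speed,
min_gross_speed     per-step speed statistics (um / s)
==================  =============================================

Movement statistics are computed between consecutive *detections*: a
trajectory may miss frames, so each step speed is normalised by the actual
inter-detection time (frame gap / fps).  Standard deviations are sample
(n-1) SDs.  The circular SD of turning angles is the standard
directional-statistics estimator sqrt(-2 ln R) where R is the mean
resultant length of the unit vectors at the turning angles.

Alongside the 15 classifier features, each vector carries trajectory
metadata used by quality filtering: duration (s), number of detected
frames, net displacement (um), median step length (um) and detection rate
(detections / frame span).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TrajectoryTable

FEATURE_COLUMNS = [
    "mean_area",
    "sd_area",
    "mean_perimeter",
    "sd_perimeter",
    "mean_major",
    "sd_major",
    "mean_minor",
    "sd_minor",
    "mean_ar",
    "sd_ar",
    "sd_turning",
    "gross_speed",
    "sd_gross_speed",
    "max_gross_speed",
    "min_gross_speed",
]

META_COLUMNS = [
    "sample_id",
    "trajectory_id",
    "duration",
    "n_frames",
    "net_displacement",
    "median_step",
    "detection_rate",
]


class TrajectoryTooShort(ValueError):
    """Raised for trajectories with fewer than two detections."""


@dataclass
class StepSeries:
    """Per-step movement quantities of a single trajectory."""

    displacement: np.ndarray  # um, one per step
    dt: np.ndarray  # s, actual inter-detection time
    speed: np.ndarray  # um/s
    heading: np.ndarray  # rad in (-pi, pi]
    turning: np.ndarray  # rad in (-pi, pi], one per pair of steps

    @property
    def n_steps(self) -> int:
        return len(self.displacement)


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    wrapped = np.mod(a + np.pi, 2 * np.pi) - np.pi
    return np.where(wrapped == -np.pi, np.pi, wrapped)


def compute_steps(records: pd.DataFrame, fps: float) -> StepSeries:
    """Step displacements, speeds, headings and turning angles.

    ``records`` holds the frame-sorted detections of one trajectory with
    columns frame, x, y.
    """
    if len(records) < 2:
        raise TrajectoryTooShort(
            f"trajectory too short ({len(records)} detections, need >= 2)"
        )
    frame = records["frame"].to_numpy(dtype=float)
    x = records["x"].to_numpy(dtype=float)
    y = records["y"].to_numpy(dtype=float)
    dx = np.diff(x)
    dy = np.diff(y)
    displacement = np.hypot(dx, dy)
    dt = np.diff(frame) / fps
    speed = displacement / dt
    heading = np.arctan2(dy, dx)
    turning = _wrap_angle(np.diff(heading))
    return StepSeries(displacement, dt, speed, heading, turning)


def circular_sd(angles: np.ndarray) -> float:
    """Circular standard deviation, sqrt(-2 ln R), of a set of angles.

    R is the length of the mean unit vector; R -> 1 (all angles equal)
    gives 0, R -> 0 (uniform directions) diverges.  Empty input is
    undefined and returns NaN.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        return float("nan")
    rbar = np.hypot(np.mean(np.cos(angles)), np.mean(np.sin(angles)))
    rbar = min(rbar, 1.0)
    if rbar <= 0.0:
        return float("inf")
    return float(np.sqrt(-2.0 * np.log(rbar)))


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) >= 2 else float("nan")


def aggregate_features(records: pd.DataFrame, fps: float) -> dict:
    """The 15 classifier features plus metadata for one trajectory."""
    if len(records) < 2:
        raise TrajectoryTooShort(
            f"trajectory too short ({len(records)} detections, need >= 2)"
        )
    steps = compute_steps(records, fps)
    frame = records["frame"].to_numpy(dtype=float)
    span = frame[-1] - frame[0] + 1
    out: dict = {}
    for col in ("area", "perimeter", "major", "minor", "ar"):
        v = records[col].to_numpy(dtype=float)
        out[f"mean_{col}"] = float(np.mean(v))
        out[f"sd_{col}"] = float(np.std(v, ddof=1))
    out["sd_turning"] = (
        circular_sd(steps.turning) if steps.turning.size >= 1 else float("nan")
    )
    out["gross_speed"] = float(np.mean(steps.speed))
    out["sd_gross_speed"] = _sd(steps.speed)
    out["max_gross_speed"] = float(np.max(steps.speed))
    out["min_gross_speed"] = float(np.min(steps.speed))
    out["duration"] = float((frame[-1] - frame[0]) / fps)
    out["n_frames"] = int(len(records))
    out["net_displacement"] = float(
        np.hypot(
            records["x"].iloc[-1] - records["x"].iloc[0],
            records["y"].iloc[-1] - records["y"].iloc[0],
        )
    )
    out["median_step"] = float(np.median(steps.displacement))
    out["detection_rate"] = float(len(records) / span)
    return out


def features_from_table(
    table: TrajectoryTable, min_frames: int = 2
) -> pd.DataFrame:
    """Feature vectors for every trajectory in a table.

    Trajectories with fewer than ``min_frames`` detections are silently
    dropped (a single detection defines no movement at all).
    """
    rows = []
    for (sample_id, trajectory_id), grp in table.groups():
        grp = grp.sort_values("frame")
        if len(grp) < min_frames:
            continue
        feats = aggregate_features(grp, table.fps)
        feats["sample_id"] = sample_id
        feats["trajectory_id"] = trajectory_id
        rows.append(feats)
    df = pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_COLUMNS)
    return df
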