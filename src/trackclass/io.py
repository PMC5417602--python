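"""Readers and writers for trajectory tables, sample metadata and features.

Tables are plain delimited text (comma by default, tab accepted) matching
the output of upstream video-tracking tools: one row per particle per frame
with positions and ellipse-fit morphology.  Coordinates use the image
convention — origin top-left, y increasing downward, 0-based frame indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default spatial calibration (um per pixel) of the video setup:
#: an 81 um displacement corresponds to 20 pixels.
DEFAULT_PIXEL_SCALE = 81.0 / 20.0  # = 4.05

TRAJECTORY_COLUMNS = [
    "sample_id",
    "trajectory_id",
    "frame",
    "x",
    "y",
    "area",
    "perimeter",
    "major",
    "minor",
    "ar",
]

METADATA_COLUMNS = [
    "sample_id",
    "microcosm_id",
    "day",
    "temperature",
    "richness",
    "composition",
    "dilution",
]


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class IntegrityError(ValueError):
    """Row-level constraint violation (duplicate keys, bad ordering...)."""


@dataclass
class Dialect:
    """Column naming and units of an input trajectory table."""

    delimiter: str = ","
    column_map: dict[str, str] = field(default_factory=dict)  # file col -> canonical
    coordinate_units: str = "um"  # "um" or "px"
    pixel_scale: float = DEFAULT_PIXEL_SCALE  # um per pixel, used when units == "px"


@dataclass
class TrajectoryTable:
    """Per-frame particle records for one or more video samples.

    ``df`` has the canonical :data:`TRAJECTORY_COLUMNS`; positions and
    morphology are in um / um^2 after any dialect conversion.
    """

    df: pd.DataFrame
    fps: float = 25.0
    pixel_scale: float = DEFAULT_PIXEL_SCALE

    def __post_init__(self) -> None:
        validate_trajectory_frame(self.df)

    def groups(self):
        """Iterate over ((sample_id, trajectory_id), frame-sorted records)."""
        return self.df.groupby(["sample_id", "trajectory_id"], sort=True)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    microcosm_id: str
    day: float
    temperature: float
    richness: int
    composition: frozenset[str]
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if len(self.composition) != self.richness:
            raise IntegrityError(
                f"sample {self.sample_id}: richness {self.richness} != "
                f"|composition| {len(self.composition)}"
            )
        if self.dilution < 1:
            raise IntegrityError(f"sample {self.sample_id}: dilution < 1")

    @property
    def is_control(self) -> bool:
        return self.richness == 0


def validate_trajectory_frame(df: pd.DataFrame) -> None:
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if len(df) == 0:
        return
    if (df["frame"] < 0).any():
        bad = df.index[df["frame"] < 0][0]
        raise IntegrityError(f"negative frame index at row {bad}")
    for col in ("area", "perimeter", "major", "minor"):
        if (df[col] <= 0).any():
            bad = df.index[df[col] <= 0][0]
            raise IntegrityError(f"non-positive {col} at row {bad}")
    if (df["major"] < df["minor"] - 1e-9).any():
        bad = df.index[df["major"] < df["minor"] - 1e-9][0]
        raise IntegrityError(f"major < minor at row {bad}")
    dup = df.duplicated(subset=["sample_id", "trajectory_id", "frame"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["sample_id", "trajectory_id", "frame"]]
        raise IntegrityError(
            "duplicate (sample, trajectory, frame) key "
            f"({key['sample_id']}, {key['trajectory_id']}, {key['frame']})"
        )
    # frames must be strictly increasing within each trajectory as given
    frames = df["frame"].to_numpy()
    keys = df["sample_id"].astype(str) + "\x00" + df["trajectory_id"].astype(str)
    same_traj = keys.to_numpy()[1:] == keys.to_numpy()[:-1]
    non_mono = same_traj & (np.diff(frames) <= 0)
    if non_mono.any():
        row = int(np.nonzero(non_mono)[0][0]) + 1
        raise IntegrityError(
            f"non-monotone frame order within trajectory at row {row} "
            f"(trajectory {df['trajectory_id'].iloc[row]})"
        )


def read_trajectory_table(
    path,
    dialect: Dialect | None = None,
    fps: float = 25.0,
) -> TrajectoryTable:
    """Read a delimited per-frame particle table.

    Pixel-unit dialects have x/y (and linear morphology) converted to um via
    ``dialect.pixel_scale``; areas scale with the square of it.
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep=dialect.delimiter)
    if dialect.column_map:
        df = df.rename(columns=dialect.column_map)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    df = df[TRAJECTORY_COLUMNS].copy()
    if dialect.coordinate_units == "px":
        s = dialect.pixel_scale
        for col in ("x", "y", "perimeter", "major", "minor"):
            df[col] = df[col] * s
        df["area"] = df["area"] * s * s
    elif dialect.coordinate_units != "um":
        raise SchemaError(f"unknown coordinate units {dialect.coordinate_units!r}")
    try:
        return TrajectoryTable(df, fps=fps, pixel_scale=dialect.pixel_scale)
    except IntegrityError as err:
        raise IntegrityError(f"{path}: {err}") from None


def parse_composition(raw, sep: str = ";") -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return frozenset()
    return frozenset(s.strip() for s in str(raw).split(sep) if s.strip())


def read_sample_metadata(path, delimiter: str = ",") -> list[SampleMeta]:
    """Read sample metadata; composition is a ';'-separated species list."""
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns and c != "dilution"]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                microcosm_id=str(row["microcosm_id"]),
                day=float(row["day"]),
                temperature=float(row["temperature"]),
                richness=int(row["richness"]),
                composition=parse_composition(row.get("composition")),
                dilution=float(row.get("dilution", 1.0)),
            )
        )
    return metas


def metadata_frame(metas: list[SampleMeta]) -> pd.DataFrame:
    """Tabular view of SampleMeta records, indexed by sample_id."""
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metas],
            "microcosm_id": [m.microcosm_id for m in metas],
            "day": [m.day for m in metas],
            "temperature": [m.temperature for m in metas],
            "richness": [m.richness for m in metas],
            "composition": [";".join(sorted(m.composition)) for m in metas],
            "dilution": [m.dilution for m in metas],
        }
    )
    return df.set_index("sample_id", drop=False)


def write_sample_metadata(metas: list[SampleMeta], path) -> None:
    metadata_frame(metas).to_csv(path, index=False)


def write_feature_table(features: pd.DataFrame, path) -> None:
    """Write trajectory features; round-trip stable at full float precision."""
    if len(features) == 0:
        warnings.warn(f"writing empty feature table to {path}", stacklevel=2)
    features.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    # round_trip parsing: read(write(x)) is bit-identical
    return pd.read_csv(path, float_precision="round_trip")


def write_trajectory_table(table: TrajectoryTable, path) -> None:
    table.df.to_csv(path, index=False)
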