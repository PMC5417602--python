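"""Synthetic microcosm experiments for end-to-end pipeline testing.

Generates per-frame particle tables that mimic video-tracked ciliate
communities: each species is an archetype with baseline morphology
(ellipse axes, area, perimeter, aspect ratio) and movement (speed, turning
concentration), modified multiplicatively by

* a temperature slope (cells are smaller when warmer),
* a species-specific temporal drift (sizes shrink over the experiment at
  different rates — the mechanism that makes globally-trained classifiers
  fail), and
* lognormal individual- and frame-level variation (positivity preserved).

Movement is a correlated random walk: headings accumulate wrapped-normal
increments whose spread is the species' turning SD; step lengths come from
per-frame speeds.  Spurious "noise" trajectories emulate drifting debris:
a slow directed drift plus jitter, small erratically-measured shapes —
slow enough to fail the training-stringency speed floor yet often passing
the test-stringency filter, exactly the population the control samples
anchor.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DEFAULT_TEMPERATURES
from .io import SampleMeta, TrajectoryTable
from .noise import NOISE_LABEL

REF_TEMPERATURE = 20.0  # degC at which archetype baselines apply


@dataclass(frozen=True)
class SpeciesArchetype:
    name: str
    major_um: float  # baseline mean major axis
    aspect_ratio: float
    speed_um_s: float  # baseline mean gross speed
    turn_sd_rad: float  # heading-increment SD (turning concentration^-1/2)
    size_drift_per_day: float = 0.0  # fractional change per day, e.g. -0.02
    size_temp_slope: float = -0.02  # fractional change per degC above 20
    cv_between: float = 0.12  # individual-to-individual size variation
    cv_within: float = 0.05  # frame-to-frame measurement variation
    speed_cv: float = 0.25
    abundance_mean: float = 40.0  # expected trajectories per sample
    abundance_sigma: float = 0.4  # lognormal spread of that expectation

    def size_multiplier(self, day: float, temperature: float) -> float:
        return (1.0 + self.size_drift_per_day) ** day * (
            1.0 + self.size_temp_slope
        ) ** (temperature - REF_TEMPERATURE)


def default_archetypes() -> dict[str, SpeciesArchetype]:
    """Six archetypes spanning the ca. 30-400 um ciliate size gradient."""
    specs = [
        #        name    major   ar  speed  turn   drift/day
        ("Tetra", 35.0, 1.8, 350.0, 0.80, -0.010),
        ("Dexio", 48.0, 2.0, 300.0, 0.70, -0.006),
        ("Colp", 70.0, 1.9, 450.0, 0.55, -0.004),
        ("Loxo", 90.0, 2.2, 400.0, 0.60, -0.008),
        ("Para", 180.0, 2.8, 800.0, 0.40, -0.003),
        ("Spiro", 350.0, 6.0, 250.0, 0.30, -0.002),
    ]
    return {
        name: SpeciesArchetype(
            name=name,
            major_um=major,
            aspect_ratio=ar,
            speed_um_s=speed,
            turn_sd_rad=turn,
            size_drift_per_day=drift,
        )
        for name, major, ar, speed, turn, drift in specs
    }


#: Drifting-debris archetype: slow directed drift, erratic small shapes.
NOISE_ARCHETYPE = SpeciesArchetype(
    name=NOISE_LABEL,
    major_um=22.0,
    aspect_ratio=1.4,
    speed_um_s=70.0,
    turn_sd_rad=1.6,
    size_drift_per_day=0.0,
    size_temp_slope=0.0,
    cv_between=0.35,
    cv_within=0.25,
    speed_cv=0.4,
    abundance_mean=25.0,
    abundance_sigma=0.4,
)


@dataclass
class SynthConfig:
    archetypes: dict[str, SpeciesArchetype] = field(default_factory=default_archetypes)
    noise_archetype: SpeciesArchetype = NOISE_ARCHETYPE
    temperatures: tuple[float, ...] = (21.0,)
    sampling_days: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    communities: tuple[frozenset, ...] = ()  # multi-species test communities
    video_length_s: float = 5.0
    fps: float = 25.0
    dropout: float = 0.05  # iid per-frame detection failure probability
    noise_rate: float = 0.4  # noise trajectories per sample, as a fraction
    #                          of the sample's organism count (controls use
    #                          the noise archetype's own abundance)
    arena_um: float = 8000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.video_length_s <= 0:
            raise ValueError("fps and video length must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.noise_rate < 0:
            raise ValueError("noise rate must be >= 0")


def _ellipse_perimeter(major: np.ndarray, minor: np.ndarray) -> np.ndarray:
    # Ramanujan approximation on semi-axes
    a, b = major / 2.0, minor / 2.0
    return np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))


def _lognorm(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Unit-mean lognormal multiplier with coefficient of variation ~cv."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return rng.lognormal(-sigma * sigma / 2.0, sigma, size=size)


def generate_trajectory(
    rng: np.random.Generator,
    archetype: SpeciesArchetype,
    day: float = 0.0,
    temperature: float = REF_TEMPERATURE,
    fps: float = 25.0,
    length_s: float = 5.0,
    dropout: float = 0.05,
    arena_um: float = 8000.0,
    as_noise: bool = False,
) -> pd.DataFrame:
    """Per-frame records (frame, x, y, morphology) of one particle.

    ``as_noise`` switches the movement model from a correlated random walk
    to slow directed drift with jitter (debris carried by liquid flow).
    """
    n = max(2, int(round(length_s * fps)))
    mult = archetype.size_multiplier(day, temperature)
    m_size = _lognorm(rng, archetype.cv_between)
    m_speed = _lognorm(rng, archetype.cv_between)
    major_mean = archetype.major_um * mult * m_size
    ar_mean = max(1.05, archetype.aspect_ratio * _lognorm(rng, archetype.cv_between / 2))

    major = major_mean * _lognorm(rng, archetype.cv_within, n)
    ar = np.maximum(1.0 + 1e-6, ar_mean * _lognorm(rng, archetype.cv_within / 2, n))
    minor = major / ar
    area = np.pi / 4.0 * major * minor * _lognorm(rng, archetype.cv_within, n)
    perimeter = _ellipse_perimeter(major, minor) * _lognorm(
        rng, archetype.cv_within / 2, n
    )

    dt = 1.0 / fps
    x = np.empty(n)
    y = np.empty(n)
    x[0] = rng.uniform(0, arena_um)
    y[0] = rng.uniform(0, arena_um)
    if as_noise:
        drift_dir = rng.uniform(-np.pi, np.pi)
        drift_speed = archetype.speed_um_s * m_speed * 0.7
        jitter = archetype.speed_um_s * 0.5 * dt
        steps_x = drift_speed * dt * np.cos(drift_dir) + rng.normal(0, jitter, n - 1)
        steps_y = drift_speed * dt * np.sin(drift_dir) + rng.normal(0, jitter, n - 1)
        x[1:] = x[0] + np.cumsum(steps_x)
        y[1:] = y[0] + np.cumsum(steps_y)
    else:
        heading = rng.uniform(-np.pi, np.pi) + np.cumsum(
            np.concatenate([[0.0], rng.normal(0, archetype.turn_sd_rad, n - 2)])
        )
        speed = (
            archetype.speed_um_s
            * m_speed
            * _lognorm(rng, archetype.speed_cv, n - 1)
        )
        x[1:] = x[0] + np.cumsum(speed * dt * np.cos(heading))
        y[1:] = y[0] + np.cumsum(speed * dt * np.sin(heading))

    frames = np.arange(n)
    if dropout > 0:
        keep = rng.random(n) >= dropout
        if keep.sum() < 2:
            keep[:2] = True
        frames, x, y = frames[keep], x[keep], y[keep]
        major, minor, ar = major[keep], minor[keep], ar[keep]
        area, perimeter = area[keep], perimeter[keep]
    return pd.DataFrame(
        {
            "frame": frames,
            "x": x,
            "y": y,
            "area": area,
            "perimeter": perimeter,
            "major": major,
            "minor": minor,
            "ar": ar,
        }
    )


def _sample_records(
    rng: np.random.Generator,
    config: SynthConfig,
    sample_id: str,
    species_counts: dict[str, int],
    n_noise: int,
    day: float,
    temperature: float,
) -> tuple[list[pd.DataFrame], list[tuple[str, str, str]]]:
    frames, truth = [], []
    counter = 0
    jobs = [
        (sp, config.archetypes[sp], False)
        for sp, cnt in sorted(species_counts.items())
        for _ in range(cnt)
    ] + [(NOISE_LABEL, config.noise_archetype, True) for _ in range(n_noise)]
    for label, arch, as_noise in jobs:
        traj = generate_trajectory(
            rng,
            arch,
            day=day,
            temperature=temperature,
            fps=config.fps,
            length_s=config.video_length_s,
            dropout=config.dropout,
            arena_um=config.arena_um,
            as_noise=as_noise,
        )
        tid = f"t{counter:05d}"
        counter += 1
        traj.insert(0, "trajectory_id", tid)
        traj.insert(0, "sample_id", sample_id)
        frames.append(traj)
        truth.append((sample_id, tid, label))
    return frames, truth


def _draw_count(rng: np.random.Generator, arch: SpeciesArchetype) -> int:
    s = arch.abundance_sigma
    lam = arch.abundance_mean * rng.lognormal(-s * s / 2.0, s)
    return int(rng.poisson(lam))


@dataclass
class SyntheticExperiment:
    trajectories: TrajectoryTable
    metadata: list[SampleMeta]
    truth: pd.DataFrame  # sample_id, trajectory_id, species

    @property
    def metadata_by_id(self) -> dict[str, SampleMeta]:
        return {m.sample_id: m for m in self.metadata}


def generate_experiment(config: SynthConfig) -> SyntheticExperiment:
    """Monocultures, controls and multi-species communities per design.

    For every (temperature, sampling day): one control sample (noise
    trajectories only), one monoculture per archetype, and one sample per
    configured community composition.  Ground-truth species labels are
    returned per trajectory.
    """
    rng = np.random.default_rng(config.seed)
    all_frames: list[pd.DataFrame] = []
    all_truth: list[tuple[str, str, str]] = []
    metas: list[SampleMeta] = []

    def add_sample(sid, microcosm, counts, n_noise, day, temp, richness, comp):
        frames, truth = _sample_records(rng, config, sid, counts, n_noise, day, temp)
        all_frames.extend(frames)
        all_truth.extend(truth)
        metas.append(
            SampleMeta(
                sample_id=sid,
                microcosm_id=microcosm,
                day=day,
                temperature=temp,
                richness=richness,
                composition=frozenset(comp),
            )
        )

    for temp in config.temperatures:
        for day in config.sampling_days:
            tag = f"T{temp:g}_d{day:g}"
            add_sample(
                f"ctrl_{tag}",
                f"ctrl_T{temp:g}",
                {},
                max(2, _draw_count(rng, config.noise_archetype)),
                day,
                temp,
                0,
                (),
            )
            for sp in sorted(config.archetypes):
                arch = config.archetypes[sp]
                counts = {sp: max(2, _draw_count(rng, arch))}
                n_noise = int(round(config.noise_rate * counts[sp]))
                add_sample(
                    f"mono_{sp}_{tag}",
                    f"mono_{sp}_T{temp:g}",
                    counts,
                    n_noise,
                    day,
                    temp,
                    1,
                    (sp,),
                )
            for ci, comp in enumerate(config.communities):
                comp = sorted(comp)
                counts = {
                    sp: max(2, _draw_count(rng, config.archetypes[sp])) for sp in comp
                }
                n_noise = int(round(config.noise_rate * sum(counts.values())))
                add_sample(
                    f"comm{ci}_{tag}",
                    f"comm{ci}_T{temp:g}",
                    counts,
                    n_noise,
                    day,
                    temp,
                    len(comp),
                    comp,
                )

    df = pd.concat(all_frames, ignore_index=True)
    table = TrajectoryTable(df, fps=config.fps)
    truth = pd.DataFrame(all_truth, columns=["sample_id", "trajectory_id", "species"])
    return SyntheticExperiment(trajectories=table, metadata=metas, truth=truth)


def with_crossing_sizes(
    archetypes: dict[str, SpeciesArchetype] | None = None,
) -> dict[str, SpeciesArchetype]:
    """Two-species variant whose size distributions cross mid-experiment.

    Species A starts large and shrinks fast; species B starts smaller and
    barely changes, so their areas overlap around the middle of a 60-day
    run.  Movement traits are kept identical so size carries nearly all the
    class signal — the regime where a sliding window matters most.
    """
    base = (archetypes or default_archetypes())["Colp"]
    a = replace(
        base,
        name="SpA",
        major_um=95.0,
        size_drift_per_day=-0.018,
        speed_um_s=400.0,
        turn_sd_rad=0.6,
    )
    b = replace(
        base,
        name="SpB",
        major_um=45.0,
        size_drift_per_day=0.0,
        speed_um_s=400.0,
        turn_sd_rad=0.6,
    )
    return {"SpA": a, "SpB": b}
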