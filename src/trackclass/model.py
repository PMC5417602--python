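"""Model/Results interface to the sliding-window classification pipeline.

:class:`WindowedRandomForest` is built from a trajectory feature table plus
sample metadata; :meth:`~WindowedRandomForest.fit` assembles the training
set for one target community (window selection, noise purge, balancing),
fits the preprocessing and the forest, and returns a
:class:`WindowedRFResults` carrying the out-of-bag report, the fitted
sub-models and the provenance of every stage.  Prediction and abundance
estimation hang off the results object.

The training pool is derived from the metadata: monoculture samples
(richness 1) supply species-labeled observations at training stringency;
control samples (richness 0) supply the noise class at test stringency,
because the noise the classifier must recognise at test time is exactly
what passes the test filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassifierModel, OOBReport, RFConfig, estimate_abundance, train
from .features import FEATURE_COLUMNS
from .io import SampleMeta
from .noise import NOISE_LABEL, NoiseConfig, NoiseModel, ellipse_filter, fit_noise_gmm
from .preprocess import Preprocessor
from .qc import FilterConfig, SpeciesBounds, apply_base_filter, apply_morphology_bounds
from .windowing import TrainingSet, WindowConfig, balance_classes, select_window


class WindowedRandomForest:
    """Sliding-window random-forest species classifier.

    Parameters
    ----------
    features : DataFrame
        One row per trajectory: the 15 classifier features plus the
        filtering metadata columns and ``sample_id`` / ``trajectory_id``.
    metadata : list of SampleMeta
        Sample-level design information (day, temperature, richness,
        composition) for every sample appearing in ``features``.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        metadata: list[SampleMeta],
        window: WindowConfig | None = None,
        filters: FilterConfig | None = None,
        noise: NoiseConfig | None = None,
        rf: RFConfig | None = None,
        bounds: SpeciesBounds | None = None,
        variance_target: float = 0.95,
        seed: int = 0,
    ) -> None:
        self.features = features
        self.metadata = {m.sample_id: m for m in metadata}
        missing = set(features["sample_id"]) - set(self.metadata)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        self.window = window or WindowConfig()
        self.filters = filters or FilterConfig()
        self.noise = noise or NoiseConfig()
        self.rf = rf or RFConfig(seed=seed)
        self.bounds = bounds
        self.variance_target = variance_target
        self.seed = seed
        self._pool: pd.DataFrame | None = None

    # -- training pool --------------------------------------------------
    def training_pool(self) -> pd.DataFrame:
        """Labeled, quality-filtered pool of monoculture + control features."""
        if self._pool is not None:
            return self._pool
        rows = []
        for sid, meta in self.metadata.items():
            if meta.richness > 1:
                continue
            sample_feats = self.features[self.features["sample_id"] == sid]
            if len(sample_feats) == 0:
                continue
            if meta.richness == 1:
                (label,) = meta.composition
                kept, _ = apply_base_filter(sample_feats, self.filters, "train")
                if self.bounds is not None and len(kept):
                    kept = kept.assign(species=label)
                    kept, _ = apply_morphology_bounds(kept, self.bounds, meta.day)
                else:
                    kept = kept.assign(species=label)
            else:  # control
                kept, _ = apply_base_filter(sample_feats, self.filters, "test")
                kept = kept.assign(species=NOISE_LABEL)
            kept = kept.assign(day=meta.day, temperature=meta.temperature)
            rows.append(kept)
        if not rows:
            raise ValueError("no monoculture or control samples in metadata")
        pool = pd.concat(rows, ignore_index=True)
        # training requires complete feature vectors
        pool = pool.dropna(subset=FEATURE_COLUMNS)
        self._pool = pool
        return pool

    def experiment_span(self) -> tuple[float, float]:
        days = [m.day for m in self.metadata.values()]
        return (min(days), max(days))

    # -- fitting ---------------------------------------------------------
    def fit(self, target_sample_id: str) -> "WindowedRFResults":
        """Build the windowed training set for one community and fit."""
        target = self.metadata[target_sample_id]
        pool = self.training_pool()
        stage_counts: dict[str, int] = {"pool": len(pool)}

        selected = select_window(pool, target, self.window, self.experiment_span())
        stage_counts["window"] = len(selected.features)

        prep = Preprocessor(variance_target=self.variance_target)
        scores = prep.fit_transform(selected.features, FEATURE_COLUMNS)

        labels = selected.features["species"].reset_index(drop=True)
        noise_model = None
        if self.window.include_noise_class and (labels == NOISE_LABEL).any() and (
            labels != NOISE_LABEL
        ).any():
            noise_model = fit_noise_gmm(
                scores, (labels == NOISE_LABEL).to_numpy(), self.noise
            )
            noisy = noise_model.is_noise(scores)
            labels = labels.mask(pd.Series(noisy, index=labels.index), NOISE_LABEL)
        stage_counts["noise_relabeled"] = int(
            (labels == NOISE_LABEL).sum() - (selected.features["species"] == NOISE_LABEL).sum()
        )

        # per-class confidence ellipse on the first two components
        keep = np.ones(len(labels), dtype=bool)
        for cls in labels.unique():
            m = (labels == cls).to_numpy()
            if m.sum() >= 3:
                try:
                    keep[m] = ellipse_filter(scores[m], self.noise.ellipse_coverage)
                except ValueError:
                    pass  # degenerate class cloud: keep everything
        stage_counts["ellipse"] = int(keep.sum())

        windowed = TrainingSet(
            features=selected.features.reset_index(drop=True)
            .loc[keep]
            .assign(species=labels[keep]),
            provenance=selected.provenance,
        )
        required = set(target.composition)
        if self.window.include_noise_class:
            required.add(NOISE_LABEL)
        balanced = balance_classes(
            windowed, self.window.n_per_class, self.window.seed, required or None
        )
        stage_counts["balanced"] = len(balanced.features)

        model, oob = train(
            prep.transform(balanced.features), balanced.features["species"], self.rf
        )
        model.preprocessor = prep
        model.noise_model = noise_model
        model.provenance = {**balanced.provenance, "stage_counts": stage_counts}
        return WindowedRFResults(
            parent=self,
            target=target,
            classifier=model,
            oob_report=oob,
            preprocessor=prep,
            noise_model=noise_model,
            training_set=balanced,
            stage_counts=stage_counts,
        )


@dataclass
class WindowedRFResults:
    """Fit results for one target community."""

    parent: WindowedRandomForest
    target: SampleMeta
    classifier: ClassifierModel
    oob_report: OOBReport
    preprocessor: Preprocessor
    noise_model: NoiseModel | None
    training_set: TrainingSet
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def classes(self) -> list[str]:
        return self.classifier.classes

    def predict(self, features: pd.DataFrame, apply_filter: bool = True) -> pd.DataFrame:
        """Classify test trajectories (test-stringency filter by default)."""
        feats = features
        if apply_filter:
            feats, _ = apply_base_filter(feats, self.parent.filters, "test")
        feats = feats.dropna(subset=FEATURE_COLUMNS)
        scores = self.preprocessor.transform(feats)
        out = self.classifier.predict(scores)
        out.insert(0, "trajectory_id", feats["trajectory_id"].to_numpy())
        out.insert(0, "sample_id", feats["sample_id"].to_numpy())
        return out

    def predict_target(self, apply_filter: bool = True) -> pd.DataFrame:
        feats = self.parent.features
        feats = feats[feats["sample_id"] == self.target.sample_id]
        return self.predict(feats, apply_filter=apply_filter)

    def estimate_abundance(
        self,
        predictions: pd.DataFrame,
        sampled_volume_ul: float,
        n_video_frames: int,
        dilution: float | None = None,
    ) -> pd.Series:
        feats = self.parent.features
        feats = feats[feats["sample_id"] == self.target.sample_id]
        frames = feats.set_index("trajectory_id")["n_frames"]
        return estimate_abundance(
            predictions,
            frames,
            n_video_frames=n_video_frames,
            sampled_volume_ul=sampled_volume_ul,
            dilution=self.target.dilution if dilution is None else dilution,
        )

    def summary(self) -> str:
        lines = [
            "Sliding-window random forest — classification results",
            "=" * 56,
            f"target sample     : {self.target.sample_id}",
            f"day / temperature : {self.target.day:g} / {self.target.temperature:g} degC",
            f"window            : {self.parent.window.window_days:g} d, "
            f"{self.parent.window.temperature_mode}, "
            f"{self.parent.window.species_pool_mode}",
            f"n per class       : {self.parent.window.n_per_class}",
            f"components kept   : {self.preprocessor.n_components} "
            f"({self.preprocessor.explained_variance_ratio.sum():.1%} variance)",
            f"trees             : {self.classifier.config.n_trees}",
            "",
            "stage counts      : "
            + ", ".join(f"{k}={v}" for k, v in self.stage_counts.items()),
            "",
            f"{'class':<12}{'n':>6}{'OOB success':>14}",
            "-" * 32,
        ]
        for cls in self.classes:
            lines.append(
                f"{cls:<12}{self.oob_report.per_class_n[cls]:>6}"
                f"{self.oob_report.per_class_success[cls]:>14.3f}"
            )
        lines.append("-" * 32)
        lines.append(f"{'mean':<12}{'':>6}{self.oob_report.mean_success:>14.3f}")
        return "\n".join(lines)
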