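"""Random-forest training, out-of-bag evaluation, prediction, abundance.

The classifier is a 500-tree random forest: sqrt(p) candidate features per
split, terminal nodes down to a single observation, class assigned by
majority vote over trees.  Out-of-bag (OOB) success — the fraction of
training observations correctly predicted by the trees whose bootstrap
sample excluded them — is the headline performance measure; since roughly a
third of observations are out of bag for each tree, it is an out-of-sample
estimate without a separate validation split.

Species abundances are estimated from predictions as a frame-weighted
count: each trajectory contributes the fraction of video frames on which it
was detected, so short spurious tracks carry proportionally little weight,
and the mean per-frame count converts to individuals/mL through the sampled
chamber volume and the dilution factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .design import count_to_density
from .noise import NOISE_LABEL


@dataclass
class RFConfig:
    n_trees: int = 500
    max_features: str = "sqrt"  # floor(sqrt(p)) candidate features per split
    min_node_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("need at least one tree")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")


@dataclass
class OOBReport:
    per_class_success: dict[str, float]
    per_class_n: dict[str, int]
    confusion: pd.DataFrame  # rows true class, columns OOB-predicted class

    @property
    def mean_success(self) -> float:
        return float(np.mean(list(self.per_class_success.values())))

    @property
    def overall_success(self) -> float:
        n = sum(self.per_class_n.values())
        correct = sum(
            self.per_class_success[c] * self.per_class_n[c]
            for c in self.per_class_success
        )
        return correct / n if n else float("nan")


@dataclass
class ClassifierModel:
    forest: RandomForestClassifier
    classes: list[str]
    config: RFConfig
    preprocessor: object | None = None
    noise_model: object | None = None
    provenance: dict = field(default_factory=dict)

    def predict(self, scores: np.ndarray) -> pd.DataFrame:
        """Majority-vote class and per-class vote fractions.

        Ties are broken by lexicographic class order (the class list is
        sorted), so predictions are reproducible.
        """
        scores = np.asarray(scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != self.forest.n_features_in_:
            raise ValueError(
                f"expected {self.forest.n_features_in_} components, "
                f"got shape {scores.shape}"
            )
        votes = self.forest.predict_proba(scores)
        idx = votes.argmax(axis=1)  # first (lexicographically smallest) on ties
        out = pd.DataFrame(votes, columns=self.classes)
        out.insert(0, "predicted_class", [self.classes[i] for i in idx])
        out.insert(1, "vote_fraction", votes[np.arange(len(idx)), idx])
        return out


def train(
    scores: np.ndarray,
    labels: pd.Series | np.ndarray,
    config: RFConfig | None = None,
) -> tuple[ClassifierModel, OOBReport]:
    """Fit the forest on PC scores and report per-class OOB success."""
    config = config or RFConfig()
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(str)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise ValueError(
            f"need >= 2 observations per class; got {counts.to_dict()}"
        )
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        min_samples_leaf=config.min_node_size,
        bootstrap=True,
        oob_score=True,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(scores, y)
    # per-observation OOB majority vote; rows never out of bag stay NaN
    oob = forest.oob_decision_function_
    has_oob = ~np.isnan(oob).any(axis=1) & (oob.sum(axis=1) > 0)
    pred = np.array(classes, dtype=object)[np.argmax(oob, axis=1)]
    per_class_success, per_class_n = {}, {}
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for c in classes:
        m = (y == c) & has_oob
        per_class_n[c] = int(m.sum())
        per_class_success[c] = float((pred[m] == c).mean()) if m.any() else float("nan")
        for p in classes:
            confusion.loc[c, p] = int(((y == c) & has_oob & (pred == p)).sum())
    model = ClassifierModel(forest=forest, classes=classes, config=config)
    return model, OOBReport(per_class_success, per_class_n, confusion)


def estimate_abundance(
    predictions: pd.DataFrame,
    frames_per_trajectory: pd.Series,
    n_video_frames: int,
    sampled_volume_ul: float,
    dilution: float = 1.0,
    species: list[str] | None = None,
) -> pd.Series:
    """Per-species density (individuals/mL) from trajectory predictions.

    ``predictions`` needs columns trajectory_id and predicted_class;
    ``frames_per_trajectory`` maps trajectory_id to its detection count.
    The noise class never contributes to abundance.
    """
    if n_video_frames < 1:
        raise ValueError("n_video_frames must be >= 1")
    preds = predictions.set_index("trajectory_id")["predicted_class"]
    if species is None:
        species = sorted(set(preds.unique()) - {NOISE_LABEL})
    densities = {}
    for sp in species:
        traj_ids = preds.index[preds == sp]
        mean_count = float(
            frames_per_trajectory.reindex(traj_ids).fillna(0).sum() / n_video_frames
        )
        densities[sp] = count_to_density(mean_count, sampled_volume_ul, dilution)
    return pd.Series(densities, name="density_per_ml")
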