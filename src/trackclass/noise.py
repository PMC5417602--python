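"""Control-anchored noise purging for training data.

Control samples contain no organisms, so every trajectory they yield is
spurious (drifting debris, lighting changes).  A Gaussian mixture model is
fitted jointly to candidate training trajectories and control trajectories
in the retained principal-component space; clusters dominated by control
points mark the "noise region" of feature space, and training trajectories
falling there are relabeled as noise.  A 90% confidence ellipse of a
bivariate normal fitted to the first two components then removes remaining
outliers per class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

NOISE_LABEL = "noise"


@dataclass
class NoiseConfig:
    n_clusters: int = 40
    control_dominance_threshold: float = 0.5  # strict >
    ellipse_coverage: float = 0.90
    reg_covar: float = 1e-6
    n_init: int = 1
    seed: int = 0
    #: clusters are auto-reduced to floor(n/10) when observations are few
    min_obs_per_cluster: int = 10

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if not 0 < self.control_dominance_threshold < 1:
            raise ValueError("control dominance threshold must be in (0,1)")
        if not 0 < self.ellipse_coverage < 1:
            raise ValueError("ellipse coverage must be in (0,1)")


@dataclass
class NoiseModel:
    """Fitted mixture with per-cluster noise/signal labels."""

    means: np.ndarray
    covariances: np.ndarray
    weights: np.ndarray
    control_fraction: np.ndarray
    cluster_is_noise: np.ndarray  # bool per cluster
    config: NoiseConfig = field(default_factory=NoiseConfig)
    _gmm: GaussianMixture | None = field(default=None, repr=False)

    @property
    def n_clusters(self) -> int:
        return len(self.weights)

    def predict_cluster(self, scores: np.ndarray) -> np.ndarray:
        return self._mixture().predict(np.asarray(scores, dtype=float))

    def is_noise(self, scores: np.ndarray) -> np.ndarray:
        return self.cluster_is_noise[self.predict_cluster(scores)]

    def _mixture(self) -> GaussianMixture:
        if self._gmm is None:
            gmm = GaussianMixture(
                n_components=self.n_clusters, covariance_type="full"
            )
            gmm.means_ = self.means
            gmm.covariances_ = self.covariances
            gmm.weights_ = self.weights
            gmm.precisions_cholesky_ = np.array(
                [np.linalg.cholesky(np.linalg.inv(c)).T for c in self.covariances]
            )
            self._gmm = gmm
        return self._gmm

    def to_json(self) -> str:
        return json.dumps(
            {
                "means": self.means.tolist(),
                "covariances": self.covariances.tolist(),
                "weights": self.weights.tolist(),
                "control_fraction": self.control_fraction.tolist(),
                "cluster_is_noise": self.cluster_is_noise.tolist(),
            }
        )

    @classmethod
    def from_json(cls, payload: str, config: NoiseConfig | None = None) -> "NoiseModel":
        d = json.loads(payload)
        return cls(
            means=np.array(d["means"]),
            covariances=np.array(d["covariances"]),
            weights=np.array(d["weights"]),
            control_fraction=np.array(d["control_fraction"]),
            cluster_is_noise=np.array(d["cluster_is_noise"], dtype=bool),
            config=config or NoiseConfig(),
        )


def fit_noise_gmm(
    scores: np.ndarray,
    is_control: np.ndarray,
    config: NoiseConfig | None = None,
) -> NoiseModel:
    """Fit the mixture to pooled candidate + control observations.

    Each observation is hard-assigned to its maximum-responsibility cluster;
    a cluster is labeled noise iff its control fraction strictly exceeds the
    dominance threshold.
    """
    config = config or NoiseConfig()
    scores = np.asarray(scores, dtype=float)
    is_control = np.asarray(is_control, dtype=bool)
    if scores.ndim != 2 or len(scores) != len(is_control):
        raise ValueError("scores and origin labels must align")
    if is_control.all() or not is_control.any():
        raise ValueError(
            "need both candidate and control observations to anchor noise clusters"
        )
    n = len(scores)
    k = config.n_clusters
    max_k = max(2, n // config.min_obs_per_cluster)
    if k > max_k:
        warnings.warn(
            f"reducing n_clusters from {k} to {max_k} for {n} observations",
            stacklevel=2,
        )
        k = max_k
    if n <= k:
        raise ValueError(f"need more observations ({n}) than clusters ({k})")
    gmm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=config.reg_covar,
        n_init=config.n_init,
        init_params="k-means++",
        random_state=config.seed,
    )
    assignment = gmm.fit_predict(scores)
    control_fraction = np.array(
        [
            is_control[assignment == c].mean() if (assignment == c).any() else 0.0
            for c in range(k)
        ]
    )
    cluster_is_noise = control_fraction > config.control_dominance_threshold
    model = NoiseModel(
        means=gmm.means_,
        covariances=gmm.covariances_,
        weights=gmm.weights_,
        control_fraction=control_fraction,
        cluster_is_noise=cluster_is_noise,
        config=config,
    )
    model._gmm = gmm
    return model


def reclassify_training(
    labels: pd.Series, scores: np.ndarray, model: NoiseModel
) -> pd.Series:
    """Relabel training observations in noise clusters as the noise class.

    Features are untouched; only the class label changes.
    """
    noisy = model.is_noise(scores)
    out = labels.copy()
    out[noisy] = NOISE_LABEL
    return out


def ellipse_filter(scores2d: np.ndarray, coverage: float = 0.90) -> np.ndarray:
    """Inlier mask of the bivariate-normal confidence ellipse.

    Fits mean and covariance to the first two component scores and keeps
    points whose squared Mahalanobis distance is within the chi-square(2)
    quantile at the requested coverage.
    """
    X = np.asarray(scores2d, dtype=float)[:, :2]
    if len(X) < 3:
        raise ValueError("need at least 3 observations to fit an ellipse")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    det = np.linalg.det(cov)
    if not np.isfinite(det) or det <= 1e-300:
        raise ValueError(
            "singular covariance for ellipse fit; check for duplicated or "
            "collinear component scores"
        )
    inv = np.linalg.inv(cov)
    d = X - mean
    md2 = np.einsum("ij,jk,ik->i", d, inv, d)
    return md2 <= stats.chi2.ppf(coverage, df=2)
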