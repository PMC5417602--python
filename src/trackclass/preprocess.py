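"""Feature preprocessing: sanitation, Box-Cox, standardisation, PCA.

Fitted on training data only and frozen for test data.  The order is
Box-Cox -> center/scale -> PCA: the power transform requires strictly
positive inputs, so it must precede zero-centering.  Features with missing
values or zero variance in the training data are dropped outright.  PCA is
run on the standardised features (equivalently, correlation PCA) and the
smallest number of leading components whose cumulative explained variance
reaches the target (default 95%) is retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

#: Positivity margin added to shifted features before Box-Cox.
_SHIFT_EPS = 1e-6


@dataclass
class Preprocessor:
    """Frozen Box-Cox + standardise + PCA transform (the preprocess model)."""

    variance_target: float = 0.95
    # fitted state
    kept_features: list[str] = field(default_factory=list)
    dropped_features: list[str] = field(default_factory=list)
    shifts: np.ndarray | None = None
    lambdas: np.ndarray | None = None
    centers: np.ndarray | None = None
    scales: np.ndarray | None = None
    components: np.ndarray | None = None  # (n_components, n_features)
    explained_variance_ratio: np.ndarray | None = None
    n_components: int = 0

    def fit(self, features: pd.DataFrame, feature_cols: list[str]) -> "Preprocessor":
        if len(features) < 2:
            raise ValueError("need at least 2 observations to fit preprocessing")
        kept, dropped = [], []
        for col in feature_cols:
            v = features[col]
            if v.isna().any() or float(np.std(v.to_numpy(dtype=float))) == 0.0:
                dropped.append(col)
            else:
                kept.append(col)
        if not kept:
            raise ValueError("all features are constant or have missing data")
        self.kept_features = kept
        self.dropped_features = dropped

        # canonical memory layout: reductions are then bit-reproducible
        # regardless of how the caller's frame is stored internally
        X = np.ascontiguousarray(features[kept].to_numpy(dtype=float))
        n, p = X.shape
        self.shifts = np.zeros(p)
        self.lambdas = np.zeros(p)
        Xt = np.empty_like(X)
        for j in range(p):
            col = X[:, j]
            mn = col.min()
            shift = _SHIFT_EPS + abs(mn) if mn <= 0 else 0.0
            self.shifts[j] = shift
            transformed, lam = stats.boxcox(col + shift)
            self.lambdas[j] = lam
            Xt[:, j] = transformed
        self.centers = Xt.mean(axis=0)
        self.scales = Xt.std(axis=0, ddof=1)
        self.scales[self.scales == 0] = 1.0
        Z = (Xt - self.centers) / self.scales

        pca = PCA(svd_solver="full")
        pca.fit(Z)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, self.variance_target - 1e-12) + 1)
        k = min(k, len(cum))
        self.components = pca.components_[:k]
        self.explained_variance_ratio = pca.explained_variance_ratio_[:k]
        self.n_components = k
        return self

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        if self.components is None:
            raise ValueError("preprocessor not fitted")
        missing = [c for c in self.kept_features if c not in features.columns]
        if missing:
            raise ValueError(f"missing kept feature columns: {missing}")
        X = np.ascontiguousarray(features[self.kept_features].to_numpy(dtype=float))
        Xt = np.empty_like(X)
        for j in range(X.shape[1]):
            shifted = X[:, j] + self.shifts[j]
            # clip to the strictly positive domain of the power transform
            shifted = np.maximum(shifted, _SHIFT_EPS)
            lam = self.lambdas[j]
            if abs(lam) < 1e-12:
                Xt[:, j] = np.log(shifted)
            else:
                Xt[:, j] = (shifted**lam - 1.0) / lam
        Z = (Xt - self.centers) / self.scales
        return Z @ self.components.T

    def fit_transform(self, features: pd.DataFrame, feature_cols: list[str]) -> np.ndarray:
        return self.fit(features, feature_cols).transform(features)

    # -- serialisation --------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "variance_target": self.variance_target,
                "kept_features": self.kept_features,
                "dropped_features": self.dropped_features,
                "shifts": self.shifts.tolist(),
                "lambdas": self.lambdas.tolist(),
                "centers": self.centers.tolist(),
                "scales": self.scales.tolist(),
                "components": self.components.tolist(),
                "explained_variance_ratio": self.explained_variance_ratio.tolist(),
                "n_components": self.n_components,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "Preprocessor":
        d = json.loads(payload)
        obj = cls(variance_target=d["variance_target"])
        obj.kept_features = d["kept_features"]
        obj.dropped_features = d["dropped_features"]
        obj.shifts = np.array(d["shifts"])
        obj.lambdas = np.array(d["lambdas"])
        obj.centers = np.array(d["centers"])
        obj.scales = np.array(d["scales"])
        obj.components = np.array(d["components"])
        obj.explained_variance_ratio = np.array(d["explained_variance_ratio"])
        obj.n_components = d["n_components"]
        return obj


def fit_preprocessor(
    features: pd.DataFrame,
    feature_cols: list[str],
    variance_target: float = 0.95,
) -> Preprocessor:
    """Convenience constructor mirroring :meth:`Preprocessor.fit`."""
    return Preprocessor(variance_target=variance_target).fit(features, feature_cols)
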