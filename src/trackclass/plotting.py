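"""Diagnostic plots for component space and classification success."""

from __future__ import annotations

import numpy as np
from scipy import stats


def plot_pc_space(scores, labels, ax=None, coverage: float | None = 0.90):
    """Scatter trajectories on PC1/PC2, one colour per class, with an
    optional per-class confidence ellipse."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    for cls in sorted(set(labels)):
        pts = scores[labels == cls, :2]
        ax.scatter(pts[:, 0], pts[:, 1], s=8, alpha=0.6, label=str(cls))
        if coverage is not None and len(pts) >= 3:
            _add_ellipse(ax, pts, coverage)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize="small")
    return ax


def _add_ellipse(ax, pts, coverage):
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    if np.linalg.det(cov) <= 0:
        return
    vals, vecs = np.linalg.eigh(cov)
    r2 = stats.chi2.ppf(coverage, df=2)
    t = np.linspace(0, 2 * np.pi, 200)
    circle = np.stack([np.cos(t), np.sin(t)])
    ell = (vecs @ (np.sqrt(vals * r2)[:, None] * circle)).T + mean
    ax.plot(ell[:, 0], ell[:, 1], lw=1, color="grey")


def plot_oob_by_window(results: dict[float, float], ax=None):
    """Mean OOB success against window size (days)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    windows = sorted(results)
    ax.plot(windows, [results[w] for w in windows], marker="o")
    ax.set_xlabel("window size (days)")
    ax.set_ylabel("mean OOB success")
    ax.set_ylim(0, 1)
    return ax
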