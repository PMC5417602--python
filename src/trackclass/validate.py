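"""Validation against expert labels: consensus votes, confusion matrices,
sensitivity and specificity.

The reference label for each trajectory is a consensus vote across
observers (human experts plus, by default, the automatic classifier): the
label with strictly more votes than any other wins; ties leave the
trajectory without a consensus and it is discarded from further analysis.
Per class x, sensitivity = tp / (tp + fn) (individuals predicted x among
those known to be x) and specificity = tn / (tn + fp) (individuals not
predicted x among those known not to be x).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion_counts(
    predicted: pd.Series | np.ndarray,
    known: pd.Series | np.ndarray,
    cls: str,
) -> ConfusionCounts:
    """One-vs-rest confusion counts for one class."""
    predicted = np.asarray(predicted).astype(str)
    known = np.asarray(known).astype(str)
    if len(predicted) != len(known):
        raise ValueError("predicted and known labels must align")
    p = predicted == cls
    k = known == cls
    return ConfusionCounts(
        tp=int((p & k).sum()),
        fn=int((~p & k).sum()),
        fp=int((p & ~k).sum()),
        tn=int((~p & ~k).sum()),
    )


def sensitivity(cm: ConfusionCounts) -> float:
    """True-positive rate tp/(tp+fn); NaN when the class never occurs."""
    denom = cm.tp + cm.fn
    return cm.tp / denom if denom else float("nan")


def specificity(cm: ConfusionCounts) -> float:
    """True-negative rate tn/(tn+fp); NaN when every individual is the class."""
    denom = cm.tn + cm.fp
    return cm.tn / denom if denom else float("nan")


def consensus_vote(
    votes: pd.DataFrame,
    require_min_observers: int = 2,
) -> tuple[pd.Series, list]:
    """Strict-plurality consensus per trajectory.

    ``votes`` has columns trajectory_id, observer, label.  Returns the
    consensus labels (indexed by trajectory_id) and the list of discarded
    (tied) trajectory ids.  Observer order never matters.
    """
    consensus: dict = {}
    discarded: list = []
    for tid, grp in votes.groupby("trajectory_id", sort=True):
        if grp["observer"].nunique() < require_min_observers:
            raise ValueError(
                f"trajectory {tid}: need >= {require_min_observers} observers"
            )
        counts = Counter(grp["label"])
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            discarded.append(tid)
        else:
            consensus[tid] = top[0][0]
    return pd.Series(consensus, name="consensus"), discarded


def agreement_report(
    votes: pd.DataFrame,
    consensus: pd.Series,
    sample_of: pd.Series | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Per-observer per-class sensitivity/specificity against the consensus.

    Tied trajectories (absent from ``consensus``) are discarded before
    computing each observer's confusion matrix.  When ``sample_of`` maps
    trajectory ids to sample ids, the Pearson correlation of per-sample
    per-class counts between each pair is summarised as the mean
    observer-vs-consensus count correlation.
    """
    shared = votes[votes["trajectory_id"].isin(consensus.index)]
    if len(shared) == 0:
        raise ValueError("no trajectories shared between votes and consensus")
    classes = sorted(set(consensus.unique()))
    rows = []
    for observer, grp in shared.groupby("observer", sort=True):
        grp = grp.set_index("trajectory_id")
        ids = grp.index.intersection(consensus.index)
        pred = grp.loc[ids, "label"]
        known = consensus.loc[ids]
        for cls in classes:
            cm = confusion_counts(pred, known, cls)
            rows.append(
                {
                    "observer": observer,
                    "class": cls,
                    "sensitivity": sensitivity(cm),
                    "specificity": specificity(cm),
                    "n_known": cm.tp + cm.fn,
                }
            )
    report = pd.DataFrame(rows)

    count_r = None
    if sample_of is not None:
        def per_sample_counts(labels: pd.Series) -> np.ndarray:
            df = pd.DataFrame(
                {"sample": sample_of.reindex(labels.index), "label": labels}
            )
            tab = pd.crosstab(df["sample"], df["label"]).reindex(
                columns=classes, fill_value=0
            )
            return tab.to_numpy().ravel().astype(float)

        ref = per_sample_counts(consensus)
        rs = []
        for _, grp in shared.groupby("observer", sort=True):
            obs_labels = grp.set_index("trajectory_id")["label"].reindex(
                consensus.index
            )
            v = per_sample_counts(obs_labels.dropna())
            if np.std(v) > 0 and np.std(ref) > 0:
                rs.append(float(np.corrcoef(ref, v)[0, 1]))
        count_r = float(np.mean(rs)) if rs else None
    return report, count_r
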