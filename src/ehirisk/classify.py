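"""ROC analysis, G-mean threshold selection and race-level aggregation.

A runner is classified as a predicted incident when its probability is at
or above the decision threshold (ties to positive).  The threshold is
chosen on a fixed grid {0, step, ..., 1} as the value maximising the
geometric mean of sensitivity and specificity,

    G-mean = sqrt(TPR * (1 - FPR)),

returning the smallest maximiser (favouring sensitivity, appropriate for a
screening application).  Because the class adjustment is strictly monotone,
the AUC is identical on the model-probability and absolute-probability
scales; only the threshold value changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

__all__ = ["RocSummary", "roc_auc", "gmean_threshold", "confusion",
           "race_level_summary"]


def _check_labels(labels):
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if not set(classes.tolist()) <= {0, 1} or len(classes) < 2:
        raise ValueError("labels must contain both classes 0 and 1")
    return labels.astype(int)


@dataclass
class RocSummary:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    gmean_threshold: float | None = None
    confusion: dict | None = None


def roc_auc(probs, labels) -> RocSummary:
    """ROC curve over all distinct score thresholds and trapezoid AUC.

    Tied scores contribute half-concordance to the AUC (the trapezoid rule
    over the tie-collapsed curve).
    """
    labels = _check_labels(labels)
    probs = np.asarray(probs, dtype=float)
    fpr, tpr, thr = _roc_curve(labels, probs)
    return RocSummary(thresholds=thr, tpr=tpr, fpr=fpr, auc=float(_auc(fpr, tpr)))


def confusion(probs, labels, threshold: float) -> dict:
    """2x2 counts and rates under the rule prob >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    labels = np.asarray(labels).astype(int)
    pred = np.asarray(probs, dtype=float) >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    pos = tp + fn
    neg = fp + tn
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "tpr": tp / pos if pos else np.nan,
        "fpr": fp / neg if neg else np.nan,
        "precision": tp / (tp + fp) if (tp + fp) else np.nan,
    }


def gmean_threshold(probs, labels, step: float = 0.01) -> float:
    """Smallest grid threshold maximising sqrt(TPR * (1 - FPR)).

    The grid is {0, step, 2 step, ..., 1}; classification is positive at
    prob >= t.
    """
    labels = _check_labels(labels)
    probs = np.asarray(probs, dtype=float)
    n_steps = int(round(1.0 / step))
    grid = np.linspace(0.0, 1.0, n_steps + 1)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    # vectorised counts per grid point
    tp = (probs[pos][None, :] >= grid[:, None]).sum(axis=1)
    fp = (probs[~pos][None, :] >= grid[:, None]).sum(axis=1)
    tpr = tp / n_pos
    fpr = fp / n_neg
    g = np.sqrt(tpr * (1.0 - fpr))
    return float(grid[int(np.argmax(g))])  # argmax returns the first (smallest)


def race_level_summary(probs, labels, race_ids, threshold: float) -> dict:
    """Race-level 2x2 counts: a race is predicted positive when any runner
    is at or above the threshold, observed positive when any runner has an
    incident."""
    df = pd.DataFrame({
        "race": np.asarray(race_ids),
        "pred": np.asarray(probs, dtype=float) >= threshold,
        "obs": np.asarray(labels).astype(int) == 1,
    })
    g = df.groupby("race").agg(pred=("pred", "any"), obs=("obs", "any"))
    tp = int((g.pred & g.obs).sum())
    fp = int((g.pred & ~g.obs).sum())
    fn = int((~g.pred & g.obs).sum())
    tn = int((~g.pred & ~g.obs).sum())
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "precision": tp / (tp + fp) if (tp + fp) else np.nan,
        "tpr": tp / (tp + fn) if (tp + fn) else np.nan,
    }
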